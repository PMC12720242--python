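"""Build the vibronic absorption presets and their oscillator-strength form.

The three spectrokinetic species of the OCP photocycle are modelled as
two-mode Franck-Condon progressions on the canthaxanthin C=C
(1517 cm^-1) and C-C (1157 cm^-1) stretches.
"""

import numpy as np

from ocphot.action import vibronic_markers
from ocphot.spectra import nm_to_wavenumber, to_abs_oscillator_strength
from ocphot.synthetic import default_grid, make_vibronic_spectrum, ocp_species_presets

grid = default_grid()
for name, spec in ocp_species_presets().items():
    s = make_vibronic_spectrum(spec, grid)
    f = to_abs_oscillator_strength(s)
    peak = grid[np.argmax(f.values)]
    print(f"{name}: 0-0 origin {spec.origin:.0f} cm^-1, "
          f"oscillator-strength peak at {peak:.0f} cm^-1")

ocpo = ocp_species_presets()["OCPO"]
marks = vibronic_markers(ocpo.origin, ocpo.mode1_freq)
print("OCP^O vibronic markers (0-0, 0-1, 0-2):",
      ", ".join(f"{m:.0f}" for m in marks), "cm^-1")
print(f"430 nm excitation = {nm_to_wavenumber(430):.0f} cm^-1 "
      "-> sits on the 0-2 line of the OCP^O preset")
# The 0-2 marker matching the 430 nm excitation wavenumber is the
# consistency check used when exciting the third vibronic band.
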
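# ocphot

Analysis toolkit for the photoactivation of the **orange carotenoid
protein (OCP)**, the cyanobacterial photoreceptor whose canthaxanthin
(CAN) chromophore drives the two-step photoconversion

```
OCP^O  --k1-->  OCP^I  --k2-->  OCP^R
```

from the dark-adapted orange form through a metastable intermediate to
the photoactivated red form. The package is aimed at spectroscopists
and modellers who want to analyse (or prototype analyses of) continuous
illumination photoactivation assays, polarized fluorescence
measurements, and enhanced-sampling calculations of the chromophore's
bicycle-pedal torsional coordinate — all exercisable end-to-end on
synthetic data.

## What it computes

* **Global spectrokinetic fitting** — the absorption time series
  D(ν, t) under continuous light is modelled as
  D = Σ_s c_s(t)·EADS_s(ν), with the populations c_s(t) given by the
  closed-form solution of the sequential scheme and the
  evolution-associated difference spectra (EADS) eliminated by linear
  least squares (variable projection). SVD rank analysis confirms the
  number of spectrokinetic species; fitted rates are corrected for
  actinic power and the probe-beam contribution,
  k = (k_raw − k_probe)·P_ref/P.
* **Action spectra** — k1(ν) and k2(ν) across excitation wavenumbers
  with bootstrap 95% CIs from replicates, normalized by the reactant's
  absorption oscillator strength f_abs(ν) = ε(ν)/ν to the yield-like
  ratio k_i/f_abs.
* **Fluorescence anisotropy** — from a magic-angle / perpendicular
  pair of emission spectra, r(ν) = 1 − I_⊥/I_MA (since
  I_MA ∝ I_∥ + 2I_⊥); window-averaged r with Raman-line masking
  inverts through r = (2/5)(3cos²θ − 1)/2 to the rotation angle θ of
  the emission transition dipole moment (TDM). Temperature series of θ
  and of initial photoactivation rates are fit for their sigmoidal
  onset T_on and the Arrhenius activation energy Ea above it.
* **Well-tempered metadynamics (WT-metaD)** — a desk-scale engine over
  the two periodic dihedrals CV1 = C14′–C15′–C15–C14 and
  CV2 = C15–C14–C13–C12 (the bicycle-pedal coordinate): overdamped
  Langevin dynamics in CV space, Gaussian hills with heights decaying
  as h0·exp(−V_bias/kBΔT), free-energy reconstruction
  F(s) = −((kB·T + kBΔT)/kBΔT)·V_bias(s), and minima/minimax-barrier
  analysis of the surface.
* **Chromophore geometry** — PDB parsing, IUPAC torsions, rigid bond
  rotations generating bicycle-pedal conformers, a principal-axis TDM
  proxy, and hydrogen-bond distance/angle checks.
* **Synthetic data** — Franck–Condon vibronic spectra (modes 1517 and
  1157 cm⁻¹), photoactivation series, polarized pairs with Raman
  spikes, rate–temperature tables, and analytic periodic free-energy
  landscapes; every generator is seeded and bitwise reproducible.

## Worked example

```python
import numpy as np
from ocphot.kinetics import fit_global, svd_rank
from ocphot.synthetic import (IlluminationProtocol, default_grid,
                              make_vibronic_spectrum, ocp_species_presets,
                              simulate_photoactivation_series)

grid = default_grid(spacing=50.0)
basis = [make_vibronic_spectrum(s, grid) for s in ocp_species_presets().values()]
times = np.unique(np.concatenate([np.linspace(0, 300, 20), np.linspace(0, 2000, 20)]))
protocol = IlluminationProtocol(excitation_wavenumber=21000.0,
                                sample_times=tuple(times), noise_sd=0.003)
series = simulate_photoactivation_series(basis, 0.01, 0.002, protocol, seed=1)
print(svd_rank(series)[0])
fit = fit_global(series, reference_eads=basis)
print(fit.k1, fit.k2)
```

prints

```
3
0.009939421966712329 0.0019983437115094114
```

three spectral components, and the two generating rate constants
(k1 = 0.01 s⁻¹, k2 = 0.002 s⁻¹) recovered to a fraction of a percent
from a series with 0.003 absorbance units of noise. The scripts in
`examples/` walk through each capability the same way: vibronic
presets, the kinetic fit, anisotropy → θ, temperature onsets and Ea,
the full action-spectrum campaign, metadynamics, and bicycle-pedal
geometry.

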
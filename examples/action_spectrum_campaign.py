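"""Full action-spectrum campaign: generate -> fit -> correct -> normalize.

Seven excitation wavenumbers across the absorption band, three
replicates each: global fits per series, power and probe-beam rate
corrections, bootstrap confidence intervals, and oscillator-strength
normalization to the yield-like ratio k_i/f_abs.
"""

from ocphot.pipeline import load_config, run_photoactivation_pipeline

report = run_photoactivation_pipeline(load_config({"seed": 5}))

print("nu (cm^-1)   k1 (s^-1)        k1/f_abs (unit mean)")
action = report["action"]["k1"]
for nu, k, ratio, ok in zip(action["nu"], action["k"], action["ratio"], action["ratio_mask"]):
    tag = f"{ratio:.3f}" if ok else "masked"
    print(f"{nu:9.0f}   {k:.5f}          {tag}")

rms = report["yield_recovery_rms"]
print(f"\nyield-modulation recovery RMS: k1 {rms['k1']:.4f}, k2 {rms['k2']:.4f}")
# The rising k1/f_abs ratio towards high wavenumbers reproduces the
# generating yield modulation: the reaction probability per absorbed
# photon grows above the 0-1 vibronic transition.
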
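# Methods

This note documents the models implemented in `ocphot`, the choices
made where the design was open, and what the synthetic-data tests do
and do not demonstrate about real measurements.

## Spectral axes and oscillator strengths

Wavenumber (cm⁻¹, ascending) is the canonical internal axis; nm values
are converted at I/O boundaries by ν = 10⁷/λ. Absorption spectra are
converted to oscillator-strength form as ε(ν)/ν and emission spectra
as λ²F(ν)/ν³, which with λ = 1/ν is F(ν)/ν⁵ overall. Both transforms
are defined up to a global constant; downstream uses (normalization of
action spectra, figure-style comparisons) are scale-free, and the
implementation drops the constant. Resampling is linear — at the
default 10 cm⁻¹ grid spacing the spectra are smooth on the scale of a
grid cell and spline interpolation would change results below the
noise floor. Band integrals are trapezoidal with exact interpolated
endpoints.

## Vibronic synthetic spectra

Each spectrokinetic species is generated as a two-mode Franck–Condon
progression: Gaussian lines at ν₀₀ + n₁ω₁ + n₂ω₂ with Poisson weights
e^(−S)Sⁿ/n! per mode, truncated once 99.9% of the total weight is
included (the truncation error is far below the noise levels used
anywhere). The mode wavenumbers default to the canthaxanthin resonance
Raman stretches, ω₁ = 1517 cm⁻¹ (C=C) and ω₂ = 1157 cm⁻¹ (C–C). The
species presets are **illustrative**: origins, Huang–Rhys factors
(S₁ ≈ 1, S₂ ≈ 0.5) and linewidths (850–1250 cm⁻¹ FWHM) are chosen to
give orange/intermediate/red band shapes with resolved vibronic
structure, with the OCP^O origin fixed at 23,250 − 2·1517 cm⁻¹ so that
its 0–2 line coincides with 430 nm excitation. A multimode Brownian
oscillator treatment of the true lineshapes is deliberately out of
scope; consequences: synthetic bands are symmetric Gaussian stacks
with no temperature- or solvent-dependent broadening.

## Sequential kinetics and the global fit

Populations of OCP^O → OCP^I → OCP^R under continuous light follow the
closed form O = e^(−k₁t), I = k₁/(k₂−k₁)(e^(−k₁t) − e^(−k₂t)),
R = 1 − O − I, with the analytic limit I = k₁t·e^(−k₁t) engaged when
|k₂ − k₁| ≤ 10⁻⁹k₁ to avoid catastrophic cancellation. Forward rates
scale linearly with actinic intensity; the model is forward-only — the
slow dark back-reaction of OCP^R is excluded from the
illumination-phase model.

`fit_global` uses variable projection: for a trial (k₁, k₂) the EADS
are the exact linear least-squares solution EADS = C⁺D, so the
nonlinear search runs over two log-rates only. Multi-start (5×5
log-spaced grid over [0.1/t_max, 10/t_min], best three refined by
trust-region least squares) guards against local minima. EADS are
unconstrained — no non-negativity or smoothness penalty is imposed.
Confidence intervals are linearised 95% intervals from the Jacobian in
log-rate space.

**Rate/EADS pairing ambiguity.** A sequential chain fits the data
identically with the two rates exchanged and compensating EADS. When
reference spectra for the species are available (as in the synthetic
campaign, where the reactant spectra are known from the generator —
mirroring a laboratory situation where they come from previous
characterisation), the labelling whose shape-normalised EADS best
match the references is reported. Without references the faster rate
is reported as k₁ and the result is flagged `swap_ambiguity`.

SVD rank uses a noise-floor cut: 5× the median of the trailing half of
the singular-value spectrum, with a lower bound of 10⁻¹⁰ of the
leading value so that a noiseless (machine-precision) series reports
its exact rank.

Initial rates are the early-time slope of the band-integrated
|illuminated − dark| signal (default: earliest 20% of time points,
with an R² linearity diagnostic). Rate correction subtracts the
probe-beam-only rate and rescales to the reference actinic power.

The Arrhenius fit regresses ln(rate) on 1/T (R = 1.98720425×10⁻³
kcal mol⁻¹ K⁻¹) above a caller-supplied onset threshold. For onset
*estimation* from a rate channel the package fits the joint model
A·e^(−Ea/RT)·logistic((T−T_on)/w) in the log domain: a plain logistic
cannot separate the onset from the activated growth above it, because
between 250 and 310 K the Arrhenius factor alone changes the rate by
more than an order of magnitude at Ea ≈ 8.5 kcal/mol.

## Anisotropy and TDM rotation

The measurement scheme stores a magic-angle spectrum I_MA ∝ I_∥ + 2I_⊥
and a perpendicular spectrum; from the definition
r = (I_∥ − I_⊥)/(I_∥ + 2I_⊥) it follows that r = 1 − I_⊥/I_MA
pointwise, independent of the common proportionality constant. Points
with I_MA below 10⁻³ of its maximum are masked (division noise).
Raman lines are excluded by wavenumber windows at excitation − shift
with a default half-width of 150 cm⁻¹ (line position plus resolution
broadening; configurable). Averaging over the 18,000–21,500 cm⁻¹
window (the fluorescence peak) is unweighted by default; an
intensity-weighted option exists.

The inversion θ = arccos(√((5r+1)/3)) is reported on [0°, 90°] — the
anisotropy cannot distinguish θ from 180° − θ. The library is strict
about the physical range r ∈ [−0.2, 0.4]; the pipeline clamps instead,
since noise can push window averages marginally past the limits.
Near θ = 0 the arccos inversion loses precision in the last ulp
(≈10⁻⁷ degrees) — irrelevant at any realistic noise level, but the
reason round-trip tests use the endpoint exactly or stay above 0.1°.

Temperature onsets of θ(T) are fit with a four-parameter logistic
(θ_lo, θ_hi, T_on, width); a flat series is flagged degenerate rather
than fit. The logistic was chosen for the sigmoidal response because
no functional form is canonical for a protein dynamical transition;
any similar saturating sigmoid would serve.

## Synthetic polarized pairs, rates and noise

Polarized pairs put I_⊥ = (1 − r(θ))·I_MA on the fluorescence
background and add Raman spikes with their own anisotropy (default
r = 0.4, i.e. fully polarized — configurable), so unmasked window
averages are visibly biased. Rate–temperature tables use
multiplicative lognormal noise (rates are positive). Initial-rate
series noise is additive Gaussian in absorbance units.

## Well-tempered metadynamics

The engine biases the two periodic dihedral CVs directly: overdamped
Langevin dynamics s ← s + Δt·(−∇(U + V_bias))/γ + ξ with
Var(ξ) = 2kBTΔt/γ, angles wrapped to [−180°, 180°). This replaces the
all-atom molecular sampler of a production simulation — the
well-tempered bias logic is the modelled object, the sampler is not —
so engine time units are reduced and map only nominally to ps.

Hills are isotropic Gaussians of width w = 5° by default. The
literature value w = 5.0 for this protocol carries no explicit unit;
degrees is the only reading compatible with a ±180° domain (5 radians
would exceed it), and the width is configurable. Heights follow
h = h0·exp(−V_bias(s)/kBΔT) with h0 = 0.1 kcal/mol and
kBΔT = 20 kcal/mol as defaults; "bias factor" is read as the
well-tempering *energy* kBΔT, and the conventional dimensionless
γ = 1 + kBΔT/(kBT) ≈ 34.6 at 300 K is exposed alongside. The free
energy estimate is F(s) = −((kBT + kBΔT)/kBΔT)·V_bias(s), gauge-fixed
to min F = 0.

During a run the bias and its gradient are tabulated on a periodic
grid (1.5° default) updated per hill and read by bilinear
interpolation — an O(1)-per-step exact-to-interpolation-error cache;
the hill log itself is exact, and `BiasPotential.value/gradient`
evaluate the exact Gaussian sum. Hills are also written/read in a
PLUMED-HILLS-style table for interoperability.

Minima of a free-energy grid are points below all eight periodic
neighbours, refined by per-axis quadratic fits. Barriers are minimax
path values (lowest possible ceiling) over the 8-connected periodic
grid graph, computed with a bottleneck Dijkstra search. For
reconstructed (hence rippled) surfaces, `prominent_minima` filters by
topographic prominence — the saddle height to any deeper minimum —
which separates physical basins from hill-granularity ripple.

**Convergence testing.** The engine's convergence is verified on a
compact periodic double well (6 kcal/mol wells at (±80°, 0°),
saddle ≈ 5.5 kcal/mol) with a stated hill budget of 160,000 hills
(400,000 steps, h0 = 0.01 kcal/mol, w = 10°): the reconstructed
surface agrees with the analytic one to ≤ 0.5 kcal/mol RMS over the
region within 5 kcal/mol of the minimum, for three seeds. Free
energies are defined up to an additive constant, so the two surfaces
are aligned on their mean over the comparison region before the RMS
(anchoring at the minimum instead would inject the single deepest
ripple point into every residual). Residual error scales with
√(h·fill): smaller, more frequent hills converge tighter at fixed
total bias.

## Three-well landscape preset

The preset emulating the bicycle-pedal surface places the dark
(all-trans) basin at the (±180°, ±180°)-equivalent corner, the *p*
basin (one 180° rotation, C15–C15′) at (0°, −180°) ≈ 30 kcal/mol above
dark, and the *q* bicycle-pedal basin at (0°, 0°) ≈ 7 kcal/mol above
dark, as wrapped negative Gaussians (3×3 periodic images, so surface
and gradient are smooth and exactly periodic) on a 40 kcal/mol offset.
It is a qualitative stand-in: its barrier heights are a consequence of
the Gaussian construction, not calibrated values. The FES pipeline
demo runs WT-metaD on a depth-scaled copy (×0.2, barriers of a few
kcal/mol) so that desk-scale Langevin sampling crosses all barriers
within ~160,000 steps, and reports the analytic full-depth analysis
alongside the sampled reconstruction.

## Geometry

Torsions use the standard atan2 construction with the IUPAC sign
convention; exact ±180° wraps to −180° (half-open), matching the CV
convention of the metadynamics engine. `rotate_about_bond` rotates a
rigid subset about the bond axis with the sign fixed so the
through-bond torsion changes by exactly +angle. The TDM proxy is the
principal geometric axis of the backbone atoms (leading right singular
vector of the centered coordinates); rotation angles between proxies
are sign-free, arccos|a₁·a₂| ∈ [0°, 90°], matching the anisotropy
branch ambiguity. No quantum-chemical TDM is computed. PDB I/O goes
through biotite; prime conventions in atom names (', *, ′) are
normalized to '. Hydrogens are optional in hydrogen-bond geometry
because deposited structures commonly omit them; classification
defaults are distance ≤ 3.5 Å and, when a hydrogen is present,
donor–H–acceptor angle ≥ 120°.

## Pipelines, seeds, problem sizes

The photoactivation campaign simulates 7 excitation points across the
absorbing band (19,800–23,400 cm⁻¹) × 3 replicates, with the true
rates constructed as k_i(ν) ∝ f_abs(ν)·g(ν) for a sigmoidal yield
modulation g; actinic powers cycle through 130/80/30 μW against a
130 μW reference and a probe-only rate of 2×10⁻⁴ s⁻¹, so the power and
probe corrections are genuinely exercised. Recovery of g to ≤ 3% RMS
(typically ≤ 1%) after fitting, correction, assembly and
oscillator-strength normalization is the end-to-end check. The
anisotropy campaign uses 5 K steps over 180–310 K with T_on = 240 K,
width 8 K, θ from 15° to 48°, and an Ea = 8.5 kcal/mol rate channel
with 5% lognormal noise. Fit-heavy tests use a 50 cm⁻¹ grid and ~40
time points — coarse enough to keep the suite fast, fine enough that
discretisation contributes nothing at the tested tolerances.

A single run seed fans out to per-stage child seeds by SHA-256
hashing, so stages can be rerun in isolation and full runs are
byte-identical under a fixed config and seed.

Bootstrap CIs for action spectra are percentile bootstrap over
replicates (seeded). Percentile bootstrap is known to undercover at
very small replicate counts; its coverage test therefore uses 40
replicates (coverage ≈ 94%), and with the 3 replicates of the demo
campaign the CIs should be read as approximate.

## Known limitations

* Vibronic lineshapes are symmetric Gaussian progressions; no
  solvent/temperature band-shape physics, no instrument response.
* The kinetic model is strictly sequential and forward-only; a fourth
  low-concentration compartment, if present, is not modelled.
* CV-space Langevin dynamics has no molecular kinetics: barrier
  *crossing rates* of the engine mean nothing physically; only the
  reconstructed free-energy surface is meaningful.
* The TDM proxy is geometric; electronic-structure effects on the
  transition dipole are outside scope.
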
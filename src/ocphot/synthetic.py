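"""Synthetic data generators for every stage of the photoactivation pipeline.

Each generator emulates one class of measurement from the study system:

* vibronic absorption spectra of the three spectrokinetic species
  (OCP^O, OCP^I, OCP^R) as two-mode Franck-Condon progressions built
  on the canthaxanthin C=C (~1517 cm^-1) and C-C (~1157 cm^-1)
  stretching modes;
* absorption time series under continuous illumination following the
  sequential O -> I -> R scheme with intensity-proportional rates;
* magic-angle / perpendicular polarized fluorescence pairs carrying
  highly polarized Raman spikes;
* temperature series of initial photoactivation rates: an Arrhenius
  factor gated by a sigmoidal (logistic) onset;
* analytic, doubly periodic 2D free-energy landscapes with up to three
  minima over the bicycle-pedal dihedral coordinates.

All randomness is driven by explicit seeds; a fixed seed yields
bitwise-identical output.  The spectroscopic presets are illustrative:
the study reports the mode wavenumbers but not Huang-Rhys factors or
linewidths for the OCP species.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma, log

import numpy as np
import pandas as pd

from .kinetics import R_KCAL, SpectralTimeSeries, concentrations_sequential
from .metad import FESGrid, grid_axes, wrap_angle
from .spectra import Spectrum

__all__ = [
    "VibronicSpeciesSpec",
    "IlluminationProtocol",
    "RateTemperatureModel",
    "ToyFES",
    "default_grid",
    "make_vibronic_spectrum",
    "ocp_species_presets",
    "simulate_photoactivation_series",
    "simulate_polarized_pair",
    "simulate_initial_rates",
    "make_toy_fes",
    "three_well_preset",
]

#: Canthaxanthin resonance Raman stretching modes, cm^-1.
MODE_CC_DOUBLE = 1517.0
MODE_CC_SINGLE = 1157.0

_FC_CUMULATIVE = 0.999  # truncation of the Franck-Condon progression


@dataclass(frozen=True)
class VibronicSpeciesSpec:
    """Two-mode Franck-Condon description of one spectrokinetic species.

    ``s1`` and ``s2`` are the dimensionless Huang-Rhys displacement
    factors of the two progression-forming modes; ``linewidth`` is the
    Gaussian FWHM per vibronic line in cm^-1.
    """

    name: str
    origin: float
    mode1_freq: float = MODE_CC_DOUBLE
    mode2_freq: float = MODE_CC_SINGLE
    s1: float = 1.0
    s2: float = 0.5
    linewidth: float = 900.0
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.origin, self.mode1_freq, self.mode2_freq, self.linewidth)
        if not all(np.isfinite(v) and v > 0 for v in vals):
            raise ValueError("origin, mode frequencies and linewidth must be positive and finite")
        if self.s1 < 0 or self.s2 < 0 or not np.isfinite(self.s1 + self.s2):
            raise ValueError("Huang-Rhys factors must be finite and >= 0")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")


@dataclass(frozen=True)
class IlluminationProtocol:
    """Continuous-illumination measurement protocol.

    Powers are in uW; ``probe_only_rate`` is the photoactivation rate
    driven by the white-light probe beam alone (s^-1), used downstream
    by the rate correction.  ``noise_sd`` is additive Gaussian noise in
    absorbance units.
    """

    excitation_wavenumber: float
    power: float = 150.0
    reference_power: float = 150.0
    probe_only_rate: float = 0.0
    sample_times: tuple = ()
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.power <= 0 or self.reference_power <= 0:
            raise ValueError("powers must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        t = np.asarray(self.sample_times, dtype=float)
        if t.size and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise ValueError("sample_times must be strictly ascending, first >= 0")
        object.__setattr__(self, "sample_times", tuple(float(x) for x in t))


@dataclass(frozen=True)
class RateTemperatureModel:
    """Arrhenius rate gated by a logistic temperature onset.

    rate(T) = prefactor * exp(-ea/(R*T)) * logistic((T - t_on)/onset_width)
    with ``ea`` in kcal/mol and temperatures in K.  Emulates the
    sigmoidal onset of photoactivation near the protein dynamical
    transition (~240 K for the OCP) combined with an activation energy
    of a few kcal/mol above the onset.
    """

    prefactor: float = 1.0
    ea: float = 8.5
    t_on: float = 240.0
    onset_width: float = 8.0

    def __post_init__(self) -> None:
        if self.prefactor <= 0 or self.ea < 0 or self.onset_width <= 0:
            raise ValueError("prefactor > 0, ea >= 0 and onset_width > 0 required")

    def rate(self, temperature) -> np.ndarray:
        t = np.asarray(temperature, dtype=float)
        if np.any(t <= 0):
            raise ValueError("temperatures must be positive (K)")
        from scipy.special import expit

        return self.prefactor * np.exp(-self.ea / (R_KCAL * t)) * expit((t - self.t_on) / self.onset_width)


def default_grid(lo: float = 12000.0, hi: float = 28000.0, spacing: float = 10.0) -> np.ndarray:
    """Default wavenumber grid, 12,000-28,000 cm^-1 at 10 cm^-1 spacing."""
    return np.arange(lo, hi + 0.5 * spacing, spacing)


def _fc_terms(spec: VibronicSpeciesSpec) -> list[tuple[int, int, float]]:
    """(n1, n2, weight) Poisson Franck-Condon terms, truncated at 99.9%."""

    def pois(s: float, n: int) -> float:
        if s == 0.0:
            return 1.0 if n == 0 else 0.0
        return exp(-s + n * log(s) - lgamma(n + 1))

    nmax = 30
    terms = [
        (n1, n2, pois(spec.s1, n1) * pois(spec.s2, n2))
        for n1 in range(nmax)
        for n2 in range(nmax)
    ]
    terms.sort(key=lambda t: -t[2])
    out, acc = [], 0.0
    for t in terms:
        out.append(t)
        acc += t[2]
        if acc >= _FC_CUMULATIVE:
            break
    return out


def make_vibronic_spectrum(spec: VibronicSpeciesSpec, grid) -> Spectrum:
    """Absorption spectrum of a species as a two-mode vibronic progression.

    Gaussian lines of FWHM ``spec.linewidth`` sit at
    origin + n1*mode1 + n2*mode2 with Poisson Franck-Condon weights
    e^-s s^n/n!; the progression is truncated once 99.9% of the total
    weight is included.  The result is non-negative everywhere.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be ascending with at least 2 points")
    lo_need = spec.origin - 3 * spec.linewidth
    hi_need = spec.origin + 6 * (spec.mode1_freq + spec.mode2_freq)
    if grid[-1] < lo_need or grid[0] > hi_need:
        raise ValueError("grid does not overlap the vibronic progression")
    sigma = spec.linewidth / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    values = np.zeros_like(grid)
    for n1, n2, w in _fc_terms(spec):
        center = spec.origin + n1 * spec.mode1_freq + n2 * spec.mode2_freq
        values += w * np.exp(-((grid - center) ** 2) / (2 * sigma**2))
    return Spectrum(grid, spec.amplitude * values, kind="absorbance", meta={"species": spec.name})


def ocp_species_presets() -> dict[str, VibronicSpeciesSpec]:
    """Illustrative vibronic presets for the three spectrokinetic species.

    The mode wavenumbers are the canthaxanthin Raman values (1517 and
    1157 cm^-1); origins, Huang-Rhys factors and linewidths are chosen
    so the spectra resemble the orange/intermediate/red band shapes.
    The OCP^O origin is set so its 0-2 line falls at 23,250 cm^-1
    (430 nm excitation).
    """
    return {
        "OCPO": VibronicSpeciesSpec("OCPO", origin=23250.0 - 2 * MODE_CC_DOUBLE,
                                    s1=1.1, s2=0.5, linewidth=850.0, amplitude=1.0),
        "OCPI": VibronicSpeciesSpec("OCPI", origin=19850.0,
                                    s1=1.0, s2=0.5, linewidth=950.0, amplitude=0.95),
        "OCPR": VibronicSpeciesSpec("OCPR", origin=19300.0,
                                    s1=0.9, s2=0.45, linewidth=1250.0, amplitude=0.9),
    }


def simulate_photoactivation_series(
    basis: list[Spectrum],
    k1: float,
    k2: float,
    protocol: IlluminationProtocol,
    seed: int | None = 0,
) -> SpectralTimeSeries:
    """Absorption time series of the sequential O -> I -> R photoconversion.

    The forward rates scale with the actinic light intensity,
    k_eff = k * power / reference_power, and the spectrum at each time
    is the population-weighted sum of the three basis spectra plus
    Gaussian noise of ``protocol.noise_sd``.
    """
    if len(basis) != 3:
        raise ValueError("need exactly 3 basis spectra (OCPO, OCPI, OCPR)")
    grid = basis[0].grid
    for b in basis[1:]:
        if not np.array_equal(b.grid, grid):
            raise ValueError("basis spectra must share one wavenumber grid")
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rate constants must be positive")
    times = np.asarray(protocol.sample_times, dtype=float)
    if times.size < 2:
        raise ValueError("protocol must provide at least 2 sample times")
    scale = protocol.power / protocol.reference_power
    conc = concentrations_sequential(k1 * scale, k2 * scale, times)
    bmat = np.vstack([b.values for b in basis])
    data = conc @ bmat
    if protocol.noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + rng.normal(0.0, protocol.noise_sd, size=data.shape)
    return SpectralTimeSeries(
        grid=grid,
        times=times,
        data=data,
        meta={
            "excitation_wavenumber": protocol.excitation_wavenumber,
            "power": protocol.power,
            "reference_power": protocol.reference_power,
            "k1_true": k1,
            "k2_true": k2,
        },
    )


def anisotropy_from_angle(theta_deg) -> np.ndarray | float:
    """Forward anisotropy relation r = (2/5) (3 cos^2(theta) - 1)/2."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    out = 0.4 * (3.0 * np.cos(th) ** 2 - 1.0) / 2.0
    return float(out) if out.ndim == 0 else out


def simulate_polarized_pair(
    theta: float,
    emission_shape: Spectrum,
    raman_lines=(),
    excitation_wavenumber: float = 23250.0,
    noise_sd: float = 0.0,
    seed: int | None = 0,
    r_spike: float = 0.4,
) -> tuple[Spectrum, Spectrum]:
    """Magic-angle and perpendicular emission spectra for a TDM angle theta.

    On the fluorescence background I_perp = (1 - r(theta)) * I_MA with
    r(theta) from the orientational factor.  Raman scattering spikes
    (shift, height, width in cm^-1) are placed at
    excitation - shift with their own, by default fully rigid,
    anisotropy ``r_spike = 0.4`` so that they bias unmasked averages.
    """
    if not 0.0 <= theta <= 90.0:
        raise ValueError("theta must be within [0, 90] degrees")
    grid = emission_shape.grid
    background = emission_shape.values
    r_bg = anisotropy_from_angle(theta)
    i_ma = background.copy()
    i_perp = (1.0 - r_bg) * background
    for shift, height, width in raman_lines:
        center = excitation_wavenumber - shift
        spike = height * np.exp(-((grid - center) ** 2) / (2 * width**2))
        i_ma += spike
        i_perp += (1.0 - r_spike) * spike
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        i_ma = i_ma + rng.normal(0.0, noise_sd, size=grid.size)
        i_perp = i_perp + rng.normal(0.0, noise_sd, size=grid.size)
    meta = {"theta_true": theta, "excitation_wavenumber": excitation_wavenumber}
    return (
        Spectrum(grid, i_ma, kind="emission", meta=dict(meta)),
        Spectrum(grid, i_perp, kind="emission", meta=dict(meta)),
    )


def simulate_initial_rates(
    model: RateTemperatureModel,
    temperatures,
    noise_frac: float = 0.0,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Initial photoactivation rates over a temperature series.

    Multiplicative lognormal noise (rates are positive) with log-sd
    ``noise_frac``.  Returns a DataFrame with columns T_K, rate_per_s.
    """
    t = np.asarray(temperatures, dtype=float)
    rates = model.rate(t)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        rates = rates * np.exp(rng.normal(0.0, noise_frac, size=t.size))
    return pd.DataFrame({"T_K": t, "rate_per_s": rates})


class ToyFES:
    """Analytic doubly periodic free-energy surface over the CV plane.

    A sum of wrapped negative Gaussians (each summed over the 3x3
    nearest periodic images, so the surface and its gradient are smooth
    and exactly 360-degree periodic) plus a constant offset.
    """

    def __init__(self, minima, offset: float = 0.0):
        minima = list(minima)
        if not minima:
            raise ValueError("at least one minimum is required")
        for _, _, depth, width in minima:
            if width <= 0:
                raise ValueError("widths must be positive")
            if depth <= 0:
                raise ValueError("depths must be positive")
        self.minima = [(float(a), float(b), float(d), float(w)) for a, b, d, w in minima]
        self.offset = float(offset)
        self._images = [(di * 360.0, dj * 360.0) for di in (-1, 0, 1) for dj in (-1, 0, 1)]

    def __call__(self, cv1, cv2):
        # wrapping first makes the surface exactly 360-periodic; the 3x3
        # image sum keeps it smooth across the wrap seam
        cv1 = wrap_angle(cv1)
        cv2 = wrap_angle(cv2)
        v = np.full(np.broadcast(cv1, cv2).shape, self.offset)
        for c1, c2, depth, w in self.minima:
            for s1, s2 in self._images:
                d1 = cv1 - c1 - s1
                d2 = cv2 - c2 - s2
                v = v - depth * np.exp(-(d1**2 + d2**2) / (2 * w**2))
        return float(v) if v.ndim == 0 else v

    def gradient(self, cv1: float, cv2: float) -> np.ndarray:
        cv1 = float(wrap_angle(cv1))
        cv2 = float(wrap_angle(cv2))
        g = np.zeros(2)
        for c1, c2, depth, w in self.minima:
            for s1, s2 in self._images:
                d1 = cv1 - c1 - s1
                d2 = cv2 - c2 - s2
                e = depth * np.exp(-(d1**2 + d2**2) / (2 * w**2)) / w**2
                g[0] += d1 * e
                g[1] += d2 * e
        return g

    def grid(self, spacing: float = 1.0) -> FESGrid:
        ax1, ax2 = grid_axes(spacing)
        return FESGrid(ax1, ax2, self(ax1[:, None], ax2[None, :]), meta={"analytic": True})

    def scaled(self, factor: float) -> "ToyFES":
        """Same landscape with every depth (and the offset) scaled."""
        return ToyFES(
            [(a, b, d * factor, w) for a, b, d, w in self.minima], offset=self.offset * factor
        )


def make_toy_fes(minima, offset: float = 0.0) -> tuple[ToyFES, FESGrid]:
    """Analytic potential callable plus its 1-degree grid evaluation."""
    fes = ToyFES(minima, offset=offset)
    return fes, fes.grid(1.0)


def three_well_preset() -> ToyFES:
    """Three-basin landscape emulating the bicycle-pedal surface.

    The dark (all-trans) state sits at the (+-180, +-180)-equivalent
    corner; the *p* basin (one 180-degree rotation, at the C15-C15'
    bond, CV1) and the bicycle-pedal *q* basin (second rotation at
    C13-C14, CV2) lie ~30 and ~7 kcal/mol above it.  A qualitative
    preset, not a reproduction of the all-atom surface.
    """
    offset = 40.0
    return ToyFES(
        [
            (-180.0, -180.0, 40.0, 32.0),   # dark, global minimum at ~0
            (0.0, -180.0, 10.0, 30.0),      # p, ~30 kcal/mol above dark
            (0.0, 0.0, 33.0, 30.0),         # q, ~7 kcal/mol above dark
        ],
        offset=offset,
    )


def _wrap(x):
    return wrap_angle(x)
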
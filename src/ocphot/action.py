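"""Photoactivation action spectra and oscillator-strength normalization.

An action spectrum reports a fitted rate constant (k1 for the
O -> I step, k2 for I -> R) as a function of the wavenumber of the
incident light, with 95% confidence intervals from replicate
measurements.  Dividing by the reactant's absorption
oscillator-strength spectrum f_abs(nu) converts the action spectrum
into a yield-like quantity k_i/f_abs: a flat ratio means the reaction
probability per absorbed photon is wavenumber-independent, while a
rising ratio reveals excess reactivity at higher excitation energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import Spectrum, resample

__all__ = [
    "ActionSpectrum",
    "assemble_action_spectrum",
    "normalize_by_oscillator_strength",
    "vibronic_markers",
]


@dataclass
class ActionSpectrum:
    """Rate constants versus excitation wavenumber for one reaction step."""

    excitation_grid: np.ndarray
    k: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    reactant: str
    n_replicates: np.ndarray
    ratio: np.ndarray | None = None       # k / f_abs, unit mean over unmasked points
    ratio_mask: np.ndarray | None = None  # True where the ratio is reliable
    meta: dict = field(default_factory=dict)


def _bootstrap_ci(values: np.ndarray, rng: np.random.Generator, n_boot: int) -> tuple[float, float]:
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    means = values[idx].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float(lo), float(hi)


def assemble_action_spectrum(
    replicates_by_excitation: dict[float, list[float]],
    reactant: str,
    n_boot: int = 2000,
    seed: int | None = 0,
) -> ActionSpectrum:
    """Combine replicate power-corrected rates into an action spectrum.

    ``replicates_by_excitation`` maps excitation wavenumber (cm^-1) to
    the replicate rate values at that point.  Point estimates are
    replicate means; 95% CIs come from a seeded percentile bootstrap
    (``n_boot`` resamples).  A single replicate yields NaN bounds — the
    CI is reported unavailable, not fabricated.  The excitation grid is
    returned ascending regardless of input order.
    """
    if len(replicates_by_excitation) < 2:
        raise ValueError("need at least 2 excitation points")
    rng = np.random.default_rng(seed)
    nus = np.array(sorted(replicates_by_excitation))
    k = np.empty(nus.size)
    lo = np.empty(nus.size)
    hi = np.empty(nus.size)
    n_rep = np.empty(nus.size, dtype=int)
    for i, nu in enumerate(nus):
        vals = np.asarray(replicates_by_excitation[nu], dtype=float)
        if vals.size == 0 or np.any(vals < 0):
            raise ValueError(f"invalid replicate set at {nu} cm^-1")
        k[i] = vals.mean()
        n_rep[i] = vals.size
        if vals.size == 1:
            lo[i] = hi[i] = np.nan
        elif np.ptp(vals) == 0.0:
            lo[i] = hi[i] = k[i]
        else:
            lo[i], hi[i] = _bootstrap_ci(vals, rng, n_boot)
    return ActionSpectrum(
        excitation_grid=nus, k=k, ci_low=lo, ci_high=hi,
        reactant=reactant, n_replicates=n_rep,
    )


def normalize_by_oscillator_strength(
    a: ActionSpectrum,
    f_abs: Spectrum,
    floor_frac: float = 0.05,
) -> ActionSpectrum:
    """Attach the yield-like ratio k/f_abs to an action spectrum.

    ``f_abs`` (the reactant's absorption oscillator-strength spectrum)
    is interpolated at each excitation point.  Points where f_abs falls
    below ``floor_frac`` of its maximum are masked — on the red edge of
    the band the division amplifies noise.  The unmasked ratio is
    rescaled to unit mean (the ordinate is arbitrary, as in the
    figures it mirrors).
    """
    if not 0.0 < floor_frac < 1.0:
        raise ValueError("floor_frac must lie in (0, 1)")
    f = resample(f_abs, a.excitation_grid, fill=0.0).values
    mask = f >= floor_frac * np.max(f_abs.values)
    if not np.any(mask):
        raise ValueError("all excitation points fall below the oscillator-strength floor")
    ratio = np.full(a.k.shape, np.nan)
    ratio[mask] = a.k[mask] / f[mask]
    mean = np.nanmean(ratio[mask])
    if mean > 0:
        ratio = ratio / mean
    a.ratio = ratio
    a.ratio_mask = mask
    a.meta["floor_frac"] = floor_frac
    return a


def vibronic_markers(origin: float, mode_freq: float, n: int = 3) -> list[float]:
    """Wavenumbers of the 0-0, 0-1, ... vibronic lines of a progression."""
    if origin <= 0 or mode_freq <= 0:
        raise ValueError("origin and mode frequency must be positive")
    return [origin + i * mode_freq for i in range(n)]
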
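"""Fluorescence anisotropy and emission-TDM rotation analysis.

The anisotropy r = (I_par - I_perp)/(I_par + 2 I_perp) encodes the
angle theta between the absorption and emission transition dipole
moments through the orientational factor

    r = (2/5) * (3 cos^2(theta) - 1) / 2.

Aligned TDMs give r = 0.4; theta = 54.7356 degrees (the magic angle)
gives r = 0; theta = 90 gives r = -0.2.  The measurement scheme here
records the magic-angle spectrum I_MA (proportional to the total
intensity, I_par + 2 I_perp) and the perpendicular spectrum, from
which r(nu) = 1 - I_perp(nu)/I_MA(nu) follows directly from the
definition.  Highly polarized Raman scattering lines from the
chromophore and the solvent are excluded by wavenumber masks before
window averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.special import expit

from .spectra import Spectrum

__all__ = [
    "MAGIC_ANGLE_DEG",
    "CAN_RAMAN_SHIFTS",
    "PolarizedSpectra",
    "AnisotropySpectrum",
    "OnsetFit",
    "anisotropy_from_angle",
    "anisotropy_from_magic_angle",
    "tdm_angle_from_anisotropy",
    "raman_mask",
    "average_anisotropy",
    "fit_temperature_onset",
]

#: theta with zero anisotropy: arccos(1/sqrt(3)) in degrees.
MAGIC_ANGLE_DEG = float(np.degrees(np.arccos(1.0 / np.sqrt(3.0))))

#: Canthaxanthin resonance Raman shifts (cm^-1): C=C and C-C stretches.
CAN_RAMAN_SHIFTS = (1517.0, 1157.0)
#: Nonresonant solvent Raman shifts (cm^-1).
SOLVENT_RAMAN_SHIFTS = {"2-MTHF": 2966.0, "water": 3500.0}


@dataclass(frozen=True)
class PolarizedSpectra:
    """A magic-angle / perpendicular pair of emission spectra."""

    i_ma: Spectrum
    i_perp: Spectrum
    excitation_wavenumber: float

    def __post_init__(self) -> None:
        if not np.array_equal(self.i_ma.grid, self.i_perp.grid):
            raise ValueError("polarized spectra must share one grid")
        if self.excitation_wavenumber <= 0:
            raise ValueError("excitation wavenumber must be positive")


@dataclass
class AnisotropySpectrum:
    """r(nu) with validity mask, window average and derived TDM angle."""

    grid: np.ndarray
    r: np.ndarray
    valid: np.ndarray
    window: tuple[float, float] | None = None
    r_avg: float | None = None
    theta: float | None = None
    meta: dict = field(default_factory=dict)


def anisotropy_from_angle(theta_deg):
    """Forward relation r(theta) = (2/5)(3 cos^2 theta - 1)/2."""
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    out = 0.4 * (3.0 * np.cos(th) ** 2 - 1.0) / 2.0
    return float(out) if out.ndim == 0 else out


def anisotropy_from_magic_angle(p: PolarizedSpectra, floor_frac: float = 1e-3) -> AnisotropySpectrum:
    """Anisotropy spectrum r(nu) = 1 - I_perp/I_MA.

    Because I_MA is proportional to the total intensity I_par + 2 I_perp,
    the definition r = (I_par - I_perp)/(I_par + 2 I_perp) reduces to
    1 - I_perp/I_MA when both spectra share the proportionality
    constant.  Points where I_MA falls below ``floor_frac`` of its
    maximum are masked invalid (division noise).
    """
    i_ma = p.i_ma.values
    i_perp = p.i_perp.values
    floor = floor_frac * np.max(i_ma)
    valid = i_ma > max(floor, 0.0)
    if not np.any(valid):
        raise ValueError("all points masked: magic-angle spectrum has no usable intensity")
    r = np.full_like(i_ma, np.nan)
    r[valid] = 1.0 - i_perp[valid] / i_ma[valid]
    return AnisotropySpectrum(
        grid=p.i_ma.grid.copy(), r=r, valid=valid,
        meta={"excitation_wavenumber": p.excitation_wavenumber},
    )


def tdm_angle_from_anisotropy(r: float, mode: str = "strict") -> float:
    """Invert the orientational factor to the TDM rotation angle (degrees).

    theta = arccos(sqrt((5 r + 1)/3)), reported on the [0, 90] branch
    (the anisotropy cannot distinguish theta from 180 - theta).  Outside
    the physical range [-0.2, 0.4] the strict mode raises; ``mode="clamp"``
    clips to the boundary instead (noise can push r slightly past the
    limits).
    """
    r = float(r)
    if not -0.2 <= r <= 0.4:
        if mode == "clamp":
            r = min(max(r, -0.2), 0.4)
        else:
            raise ValueError(f"anisotropy {r} outside the physical range [-0.2, 0.4]")
    return float(np.degrees(np.arccos(np.sqrt((5.0 * r + 1.0) / 3.0))))


def raman_mask(grid, excitation_wavenumber: float, shifts=CAN_RAMAN_SHIFTS, half_width: float = 150.0) -> np.ndarray:
    """Boolean keep-mask excluding Raman lines at excitation - shift.

    Each Raman shift (cm^-1) excludes the window
    [excitation - shift - half_width, excitation - shift + half_width].
    An empty shift list masks nothing.
    """
    grid = np.asarray(grid, dtype=float)
    keep = np.ones(grid.size, dtype=bool)
    for shift in shifts:
        if shift <= 0:
            raise ValueError("Raman shifts must be positive")
        center = excitation_wavenumber - shift
        keep &= np.abs(grid - center) > half_width
    return keep


def average_anisotropy(
    a: AnisotropySpectrum,
    window: tuple[float, float] = (18000.0, 21500.0),
    mask: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> float:
    """Window-averaged anisotropy over valid, unmasked grid points.

    The default window 18,000-21,500 cm^-1 covers the peak of the
    canthaxanthin fluorescence spectrum.  Averaging is unweighted
    unless ``weights`` (e.g. intensities) are supplied.
    """
    lo, hi = window
    sel = a.valid & (a.grid >= lo) & (a.grid <= hi)
    if mask is not None:
        sel &= mask
    if not np.any(sel):
        raise ValueError("no valid points in the averaging window")
    if weights is None:
        r_avg = float(np.mean(a.r[sel]))
    else:
        w = np.asarray(weights, dtype=float)[sel]
        r_avg = float(np.sum(w * a.r[sel]) / np.sum(w))
    a.window = (float(lo), float(hi))
    a.r_avg = r_avg
    return r_avg


@dataclass(frozen=True)
class OnsetFit:
    """Logistic temperature-onset fit theta(T)."""

    t_on: float
    width: float
    theta_lo: float
    theta_hi: float
    rms: float
    degenerate: bool
    message: str = ""


def fit_temperature_onset(temperatures, thetas) -> OnsetFit:
    """Least-squares logistic fit of a sigmoidal temperature response.

    theta(T) = theta_lo + (theta_hi - theta_lo) * logistic((T - t_on)/width).
    Works equally for TDM angles and for relative rates.  A flat series
    is flagged degenerate (theta_lo ~= theta_hi, t_on meaningless).
    """
    t = np.asarray(temperatures, dtype=float)
    y = np.asarray(thetas, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 points spanning the transition")

    span = float(np.ptp(y))
    if span < 1e-9 * max(1.0, np.max(np.abs(y))) or span == 0.0:
        return OnsetFit(
            t_on=float(np.median(t)), width=float(np.ptp(t)) or 1.0,
            theta_lo=float(np.mean(y)), theta_hi=float(np.mean(y)),
            rms=float(np.std(y)), degenerate=True, message="flat response",
        )

    def model(tt, t_on, width, lo_v, hi_v):
        return lo_v + (hi_v - lo_v) * expit((tt - t_on) / width)

    # Onset guess: temperature at which the response crosses its midpoint.
    mid = y.min() + 0.5 * span
    order = np.argsort(t)
    t_s, y_s = t[order], y[order]
    cross = np.nonzero(np.diff(np.sign(y_s - mid)))[0]
    t0 = float(t_s[cross[0]]) if cross.size else float(np.median(t))
    p0 = [t0, max(np.ptp(t) / 10.0, 1.0), float(y.min()), float(y.max())]
    try:
        popt, _ = curve_fit(model, t, y, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(
            f"temperature-onset fit did not converge (start {p0}): {err}"
        ) from err
    resid = y - model(t, *popt)
    t_on, width, lo_v, hi_v = popt
    if width < 0:  # logistic is symmetric under (width, lo, hi) -> (-width, hi, lo)
        width, lo_v, hi_v = -width, hi_v, lo_v
    return OnsetFit(
        t_on=float(t_on), width=float(width), theta_lo=float(lo_v), theta_hi=float(hi_v),
        rms=float(np.sqrt(np.mean(resid**2))),
        degenerate=bool(abs(hi_v - lo_v) < 1e-6 * max(1.0, abs(hi_v))),
    )
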
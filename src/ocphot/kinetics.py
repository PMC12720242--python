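"""Sequential three-compartment photoactivation kinetics and global fitting.

The photoactivation of the orange carotenoid protein under continuous
illumination follows the sequential scheme

    OCP^O --k1--> OCP^I --k2--> OCP^R

with forward rate constants proportional to the actinic light
intensity.  The absorption time series D(nu, t) is modelled as a
linear combination of three basis spectra (the evolution-associated
difference spectra, EADS) weighted by the closed-form compartment
populations.  :func:`fit_global` estimates (k1, k2) by variable
projection: for each trial rate pair the EADS are the exact linear
least-squares solution, so the nonlinear search runs over two
parameters only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .spectra import Spectrum, band_integral

__all__ = [
    "R_KCAL",
    "SpectralTimeSeries",
    "GlobalFitResult",
    "ArrheniusFit",
    "concentrations_sequential",
    "svd_rank",
    "fit_global",
    "correct_rate",
    "initial_rate",
    "arrhenius_fit",
    "write_series_tsv",
    "read_series_tsv",
]

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.98720425e-3

# Relative rate splitting below which the k1 == k2 limit form is used,
# avoiding catastrophic cancellation in (exp(-k1 t) - exp(-k2 t)).
_DEGENERACY_RTOL = 1e-9


@dataclass(frozen=True)
class SpectralTimeSeries:
    """Absorption spectra versus illumination time.

    ``data`` has one row per time point and one column per wavenumber.
    ``meta`` records the excitation wavenumber (cm^-1) and the beam
    power / reference power (uW) of the measurement.
    """

    grid: np.ndarray
    times: np.ndarray
    data: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        times = np.asarray(self.times, dtype=float)
        data = np.asarray(self.data, dtype=float)
        if data.shape != (times.size, grid.size):
            raise ValueError("data must be (n_times, n_wavenumbers)")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly ascending")
        if np.any(np.diff(times) <= 0) or times[0] < 0:
            raise ValueError("times must be strictly ascending and non-negative")
        if not np.all(np.isfinite(data)):
            raise ValueError("data must be finite")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "data", data)


@dataclass
class GlobalFitResult:
    """Result of the three-compartment variable-projection global fit."""

    k1: float
    k2: float
    k1_ci: tuple[float, float]
    k2_ci: tuple[float, float]
    eads: list[Spectrum]
    residual_rms: float
    n_components_used: int
    degenerate: bool = False
    message: str = ""
    #: The sequential model cannot distinguish the (k1, k2) labelling from
    #: the swapped one with exchanged EADS; compartments are reported in
    #: scheme order with k1 as the faster rate by convention of the fit start.
    swap_ambiguity: bool = True


def concentrations_sequential(k1: float, k2: float, times) -> np.ndarray:
    """Closed-form populations of the sequential O -> I -> R scheme.

    Returns an (n_times, 3) matrix with columns (O, I, R); rows sum to 1.
    Near-degenerate rates (|k2 - k1| <= 1e-9 k1) switch to the analytic
    limit I(t) = k1 t exp(-k1 t).
    """
    k1 = float(k1)
    k2 = float(k2)
    t = np.asarray(times, dtype=float)
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rate constants must be positive")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    o = np.exp(-k1 * t)
    if abs(k2 - k1) <= _DEGENERACY_RTOL * k1:
        i = k1 * t * np.exp(-k1 * t)
    else:
        i = k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    r = 1.0 - o - i
    out = np.column_stack([o, i, r])
    return np.clip(out, 0.0, 1.0)


def svd_rank(
    series: SpectralTimeSeries | np.ndarray,
    threshold_ratio: float | None = None,
) -> tuple[int, np.ndarray]:
    """Estimate the number of spectrokinetic species by SVD.

    Counts singular values at or above ``threshold_ratio * s[0]``.  When
    ``threshold_ratio`` is None the cut is estimated from the noise
    floor: 5x the median of the trailing half of the singular-value
    spectrum, but never below 1e-10 of the leading value.
    """
    data = series.data if isinstance(series, SpectralTimeSeries) else np.asarray(series, float)
    if min(data.shape) < 2:
        raise ValueError("need at least a 2x2 matrix for rank analysis")
    s = np.linalg.svd(data, compute_uv=False)
    if s[0] == 0:
        raise ValueError("degenerate (all-zero) matrix")
    if threshold_ratio is None:
        trailing = s[s.size // 2 :]
        cut = max(5.0 * float(np.median(trailing)), 1e-10 * s[0])
    else:
        cut = threshold_ratio * s[0]
    return int(np.sum(s >= cut)), s


def _projected_residual(logk: np.ndarray, times: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Residual of the variable-projection model at log-rates ``logk``."""
    logk = np.clip(logk, -46.0, 46.0)  # keep exp() finite if the search strays
    c = concentrations_sequential(np.exp(logk[0]), np.exp(logk[1]), times)
    eads, *_ = np.linalg.lstsq(c, data, rcond=None)
    return (data - c @ eads).ravel()


def fit_global(
    series: SpectralTimeSeries,
    init: tuple[float, float] | None = None,
    *,
    n_grid: int = 5,
    n_starts: int = 3,
    reference_eads: list[Spectrum] | None = None,
) -> GlobalFitResult:
    """Fit (k1, k2) and the EADS to an absorption time series.

    Multi-start variable projection: trial rate pairs on an
    ``n_grid x n_grid`` log-spaced grid spanning [0.1/t_max, 10/t_min]
    are scored by the projected residual, and the best ``n_starts``
    are refined with ``scipy.optimize.least_squares`` in log-rate space.
    Confidence intervals are the linearised 95% intervals from the
    Jacobian at the optimum.

    A sequential chain fits the data equally well with the two rates
    exchanged (and compensating EADS) — the well-known rate/EADS
    pairing ambiguity.  When ``reference_eads`` (known species spectra,
    e.g. from earlier characterisation) is given, the labelling whose
    shape-normalised EADS best match the references is reported;
    otherwise the faster rate is reported as k1 and the result is
    flagged ``swap_ambiguity``.
    """
    times = series.times
    data = series.data
    if times.size < 6:
        raise ValueError("global fit requires at least 6 time points")
    # Degenerate data: no evolution to fit.
    spread = np.max(np.std(data, axis=0))
    scale = max(np.max(np.abs(data)), 1e-300)
    if spread < 1e-12 * scale:
        k = 1.0 / max(times[-1], 1.0)
        return GlobalFitResult(
            k1=k, k2=k, k1_ci=(0.0, np.inf), k2_ci=(0.0, np.inf),
            eads=[Spectrum(series.grid, row, kind="absorbance")
                  for row in (data[0], np.zeros_like(data[0]), np.zeros_like(data[0]))],
            residual_rms=0.0, n_components_used=1, degenerate=True,
            message="static series: rates unidentifiable",
        )

    t_pos = times[times > 0]
    lo, hi = 0.1 / times[-1], 10.0 / t_pos[0]
    if init is not None:
        starts = [np.log(np.asarray(init, dtype=float))]
    else:
        ks = np.log(np.geomspace(lo, hi, n_grid))
        grid_pts = [np.array([a, b]) for a in ks for b in ks]
        scored = sorted(
            grid_pts,
            key=lambda p: float(np.sum(_projected_residual(p, times, data) ** 2)),
        )
        starts = scored[:n_starts]

    best = None
    for p0 in starts:
        sol = least_squares(
            _projected_residual, np.clip(p0, -45.0, 45.0), args=(times, data),
            bounds=(-46.0, 46.0), method="trf", xtol=1e-12, ftol=1e-12,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    k1, k2 = np.exp(best.x)

    def solve_eads(ka: float, kb: float):
        c = concentrations_sequential(ka, kb, times)
        e, *_ = np.linalg.lstsq(c, data, rcond=None)
        return c, e

    if reference_eads is not None:
        ref = np.vstack([r.values for r in reference_eads])

        def mismatch(e: np.ndarray) -> float:
            tot = 0.0
            for row, rrow in zip(e, ref):
                a = row / max(np.linalg.norm(row), 1e-300)
                b = rrow / max(np.linalg.norm(rrow), 1e-300)
                tot += min(np.sum((a - b) ** 2), np.sum((a + b) ** 2))
            return tot

        _, e_fwd = solve_eads(k1, k2)
        _, e_swp = solve_eads(k2, k1)
        if mismatch(e_swp) < mismatch(e_fwd):
            k1, k2 = k2, k1
    elif k1 < k2:
        k1, k2 = k2, k1  # report the faster step first

    c, eads_mat = solve_eads(k1, k2)
    resid = data - c @ eads_mat
    rms = float(np.sqrt(np.mean(resid**2)))

    # Linearised covariance in log-rate space -> multiplicative 95% CI on rates.
    dof = max(resid.size - best.x.size - eads_mat.size, 1)
    jtj = best.jac.T @ best.jac
    try:
        cov = 2.0 * best.cost / dof * np.linalg.inv(jtj)
        sd = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        sd = np.array([np.inf, np.inf])
    sd = np.minimum(sd, 100.0)  # cap: beyond this the CI is effectively unbounded
    ci = [(k * np.exp(-1.96 * s), k * np.exp(1.96 * s)) for k, s in zip((k1, k2), sd)]

    ill_conditioned = not np.all(np.isfinite(sd)) or np.any(sd > 5.0)
    return GlobalFitResult(
        k1=float(k1), k2=float(k2), k1_ci=ci[0], k2_ci=ci[1],
        eads=[Spectrum(series.grid, row, kind="absorbance",
                       meta={"species": name})
              for name, row in zip(("OCPO", "OCPI", "OCPR"), eads_mat)],
        residual_rms=rms, n_components_used=3,
        degenerate=bool(ill_conditioned),
        message="ill-conditioned: times do not resolve both rates" if ill_conditioned else "converged",
        swap_ambiguity=reference_eads is None,
    )


def correct_rate(k_raw: float, power: float, reference_power: float, probe_only_rate: float = 0.0) -> float:
    """Normalise a raw rate for actinic power and the probe-beam contribution.

    Subtracts the photoactivation rate driven by the white-light probe
    beam alone, then rescales to the reference actinic power:
    ``(k_raw - probe_only_rate) * reference_power / power``.
    """
    if power <= 0 or reference_power <= 0:
        raise ValueError("powers must be positive")
    if k_raw < probe_only_rate:
        raise ValueError("correction would yield a negative rate")
    return (k_raw - probe_only_rate) * reference_power / power


def initial_rate(
    series: SpectralTimeSeries,
    dark: Spectrum,
    band: tuple[float, float],
    early_fraction: float = 0.2,
) -> tuple[float, float]:
    """Initial photoactivation rate from the illuminated-minus-dark signal.

    Integrates |D(., t) - dark| over ``band`` and returns the least-squares
    slope over the earliest ``early_fraction`` of time points together
    with the R^2 linearity diagnostic (nan for a zero-change series).
    """
    if not np.array_equal(series.grid, dark.grid):
        raise ValueError("series and dark spectrum must share a grid")
    signal = np.array(
        [
            band_integral(Spectrum(series.grid, np.abs(row - dark.values), kind="absorbance"), *band)
            for row in series.data
        ]
    )
    n_early = max(3, int(np.ceil(early_fraction * series.times.size)))
    if series.times.size < 3:
        raise ValueError("need at least 3 early time points")
    t = series.times[:n_early]
    y = signal[:n_early]
    slope, intercept = np.polyfit(t, y, 1)
    ss_res = float(np.sum((y - (slope * t + intercept)) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return float(slope), r2


@dataclass(frozen=True)
class ArrheniusFit:
    ea: float            # activation energy, kcal/mol
    prefactor: float     # s^-1
    ea_ci: tuple[float, float]
    n_points: int


def arrhenius_fit(temperatures, rates, *, t_min: float = 0.0, weights=None) -> ArrheniusFit:
    """Arrhenius analysis: regress ln(rate) on 1/T above the onset.

    Points with T < ``t_min`` (below the activation threshold, where the
    sigmoidal onset suppresses the rate) are excluded.  Returns the
    activation energy Ea = -slope * R in kcal/mol with its 95% CI.
    """
    t = np.asarray(temperatures, dtype=float)
    r = np.asarray(rates, dtype=float)
    keep = t >= t_min
    t, r = t[keep], r[keep]
    if weights is not None:
        w = np.asarray(weights, dtype=float)[keep]
    else:
        w = np.ones_like(t)
    if t.size < 3:
        raise ValueError("need at least 3 points at or above t_min")
    if np.any(r <= 0):
        raise ValueError("rates must be positive for the log transform")
    x = 1.0 / t
    y = np.log(r)
    # Weighted least squares y = a + b x.
    W = np.diag(w)
    A = np.column_stack([np.ones_like(x), x])
    ata = A.T @ W @ A
    coef = np.linalg.solve(ata, A.T @ W @ y)
    resid = y - A @ coef
    dof = max(t.size - 2, 1)
    sigma2 = float(resid @ (w * resid)) / dof
    cov = sigma2 * np.linalg.inv(ata)
    slope_sd = float(np.sqrt(cov[1, 1]))
    ea = -coef[1] * R_KCAL
    half = 1.96 * slope_sd * R_KCAL
    return ArrheniusFit(
        ea=float(ea),
        prefactor=float(np.exp(coef[0])),
        ea_ci=(float(ea - half), float(ea + half)),
        n_points=int(t.size),
    )


@dataclass(frozen=True)
class RateOnsetFit:
    """Arrhenius-times-logistic fit of a rate-vs-temperature series."""

    t_on: float          # K
    width: float         # K
    ea: float            # kcal/mol
    prefactor: float     # s^-1
    rms_log: float       # residual RMS in ln(rate)


def fit_rate_onset(temperatures, rates) -> RateOnsetFit:
    """Fit rate(T) = A exp(-Ea/RT) logistic((T - T_on)/w) in the log domain.

    The initial-rate temperature response is the product of a thermally
    activated factor and a sigmoidal onset; a plain logistic fit cannot
    separate the onset from the Arrhenius growth above it, so both are
    fit jointly on ln(rate).
    """
    from scipy.optimize import curve_fit
    from scipy.special import log_expit

    t = np.asarray(temperatures, dtype=float)
    r = np.asarray(rates, dtype=float)
    if t.size < 5:
        raise ValueError("need at least 5 temperature points")
    if np.any(r <= 0):
        raise ValueError("rates must be positive")
    y = np.log(r)

    def model(tt, log_a, ea, t_on, width):
        return log_a - ea / (R_KCAL * tt) + log_expit((tt - t_on) / width)

    # starts: Arrhenius from the upper half, onset at the steepest log-slope
    upper = t >= np.median(t)
    slope, icpt = np.polyfit(1.0 / t[upper], y[upper], 1)
    order = np.argsort(t)
    dy = np.diff(y[order]) / np.diff(t[order])
    t0 = float(t[order][np.argmax(dy)])
    p0 = [icpt, -slope * R_KCAL, t0, max(np.ptp(t) / 20.0, 1.0)]
    popt, _ = curve_fit(model, t, y, p0=p0, maxfev=20000)
    resid = y - model(t, *popt)
    log_a, ea, t_on, width = popt
    return RateOnsetFit(
        t_on=float(t_on), width=float(abs(width)), ea=float(ea),
        prefactor=float(np.exp(log_a)), rms_log=float(np.sqrt(np.mean(resid**2))),
    )


def write_series_tsv(path, series: SpectralTimeSeries) -> None:
    """TSV layout: first column wavenumber, one column per time point."""
    with open(path, "w") as fh:
        meta = series.meta
        for key in ("excitation_wavenumber", "power", "reference_power"):
            if key in meta:
                fh.write(f"# {key}: {meta[key]}\n")
        fh.write("wavenumber_cm-1\t" + "\t".join(f"{t:.10g}" for t in series.times) + "\n")
        for j, nu in enumerate(series.grid):
            fh.write(f"{nu:.4f}\t" + "\t".join(f"{v:.10g}" for v in series.data[:, j]) + "\n")


def read_series_tsv(path) -> SpectralTimeSeries:
    meta: dict = {}
    rows = []
    times = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                try:
                    meta[key.strip()] = float(val)
                except ValueError:
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            if times is None:
                times = np.array([float(x) for x in parts[1:]])
                continue
            rows.append([float(x) for x in parts])
    arr = np.array(rows)
    return SpectralTimeSeries(grid=arr[:, 0], times=times, data=arr[:, 1:].T, meta=meta)
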
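"""Spectrum container, axis conversions and oscillator-strength transforms.

The canonical spectral axis throughout the package is the wavenumber
(cm^-1, ascending).  Wavelengths in nm are accepted only at I/O
boundaries via :func:`nm_to_wavenumber` / :func:`wavenumber_to_nm`.

Absorption and emission spectra are converted to oscillator-strength
form as eps(nu)/nu and lambda^2 F(nu)/nu^3 respectively; because
lambda = 1/nu the emission transform is F/nu^5 overall.  Both are
defined up to a global constant — the figures they feed use arbitrary
ordinate scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Spectrum",
    "SpectrumKind",
    "nm_to_wavenumber",
    "wavenumber_to_nm",
    "to_abs_oscillator_strength",
    "to_em_oscillator_strength",
    "resample",
    "band_integral",
    "read_spectrum",
    "write_spectrum",
]

#: Recognised spectrum kinds.
SpectrumKind = str
KINDS = frozenset(
    {
        "absorbance",
        "emission",
        "abs_oscillator_strength",
        "em_oscillator_strength",
        "anisotropy",
    }
)


@dataclass(frozen=True)
class Spectrum:
    """A spectrum sampled on an ascending wavenumber grid.

    Parameters
    ----------
    grid : ndarray
        Strictly ascending wavenumbers in cm^-1, length >= 2.
    values : ndarray
        Intensities; units depend on ``kind``.
    kind : str
        One of ``absorbance``, ``emission``, ``abs_oscillator_strength``,
        ``em_oscillator_strength``, ``anisotropy``.
    meta : dict
        Free-form provenance map.
    """

    grid: np.ndarray
    values: np.ndarray
    kind: SpectrumKind = "absorbance"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.ndim != 1 or grid.size < 2:
            raise ValueError("grid must be 1-D with at least 2 points")
        if values.shape != grid.shape:
            raise ValueError("grid and values must have identical shape")
        if not np.all(np.isfinite(grid)) or not np.all(np.isfinite(values)):
            raise ValueError("grid and values must be finite")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("grid must be strictly ascending")
        if self.kind not in KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)

    def with_values(self, values: np.ndarray, kind: SpectrumKind | None = None) -> "Spectrum":
        return replace(self, values=np.asarray(values, dtype=float), kind=kind or self.kind)

    def __len__(self) -> int:
        return self.grid.size


def nm_to_wavenumber(x):
    """Convert wavelength in nm to wavenumber in cm^-1 (1e7/x)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("wavelength must be positive")
    out = 1e7 / x
    return float(out) if out.ndim == 0 else out


def wavenumber_to_nm(x):
    """Convert wavenumber in cm^-1 to wavelength in nm (1e7/x)."""
    return nm_to_wavenumber(x)  # the map is its own inverse


def _require_positive_grid(s: Spectrum) -> None:
    if np.any(s.grid <= 0):
        raise ValueError("oscillator-strength transforms require positive wavenumbers")


def to_abs_oscillator_strength(s: Spectrum) -> Spectrum:
    """Absorption oscillator-strength spectrum eps(nu)/nu."""
    if s.kind != "absorbance":
        raise ValueError(f"expected an absorbance spectrum, got kind={s.kind!r}")
    _require_positive_grid(s)
    return s.with_values(s.values / s.grid, kind="abs_oscillator_strength")


def to_em_oscillator_strength(s: Spectrum) -> Spectrum:
    """Emission oscillator-strength spectrum lambda^2 F(nu)/nu^3 = F/nu^5."""
    if s.kind != "emission":
        raise ValueError(f"expected an emission spectrum, got kind={s.kind!r}")
    _require_positive_grid(s)
    return s.with_values(s.values / s.grid**5, kind="em_oscillator_strength")


def resample(s: Spectrum, grid2, *, fill: float | None = None) -> Spectrum:
    """Linearly interpolate a spectrum onto a new ascending grid.

    Points outside the hull of ``s.grid`` raise unless ``fill`` is given,
    in which case they take that value (zero-fill with ``fill=0.0``).
    """
    grid2 = np.asarray(grid2, dtype=float)
    outside = (grid2 < s.grid[0]) | (grid2 > s.grid[-1])
    if np.any(outside) and fill is None:
        raise ValueError(
            "resample target extends outside the source grid "
            f"[{s.grid[0]:g}, {s.grid[-1]:g}]; pass fill= to allow"
        )
    values = np.interp(grid2, s.grid, s.values)
    if fill is not None:
        values = np.where(outside, fill, values)
    return Spectrum(grid2, values, kind=s.kind, meta=dict(s.meta))


def band_integral(s: Spectrum, lo: float, hi: float) -> float:
    """Trapezoidal integral of the spectrum over the band [lo, hi] cm^-1."""
    if not lo < hi:
        raise ValueError("band requires lo < hi")
    lo = max(lo, float(s.grid[0]))
    hi = min(hi, float(s.grid[-1]))
    if lo >= hi:
        return 0.0
    inner = s.grid[(s.grid > lo) & (s.grid < hi)]
    x = np.concatenate(([lo], inner, [hi]))
    y = np.interp(x, s.grid, s.values)
    return float(np.trapezoid(y, x))


def write_spectrum(path, s: Spectrum, sep: str = ",") -> None:
    """Write a two-column text spectrum with a ``# kind:`` comment header."""
    with open(path, "w") as fh:
        fh.write(f"# kind: {s.kind}\n")
        fh.write(f"wavenumber_cm-1{sep}value\n")
        for g, v in zip(s.grid, s.values):
            fh.write(f"{g:.6f}{sep}{v:.10g}\n")


def read_spectrum(path) -> Spectrum:
    """Read a spectrum written by :func:`write_spectrum` (CSV or TSV)."""
    kind = "absorbance"
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "kind:" in line:
                    kind = line.split("kind:", 1)[1].strip()
                continue
            sep = "\t" if "\t" in line else ","
            parts = line.split(sep)
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                continue  # header row
    if len(rows) < 2:
        raise ValueError(f"no spectrum data found in {path}")
    arr = np.array(rows)
    return Spectrum(arr[:, 0], arr[:, 1], kind=kind)
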
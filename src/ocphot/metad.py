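"""Well-tempered metadynamics on two periodic dihedral collective variables.

The engine biases the two backbone dihedrals that define the
bicycle-pedal coordinate of the canthaxanthin chromophore:
CV1 = C14'-C15'-C15-C14 and CV2 = C15-C14-C13-C12, both wrapped to
[-180, 180) degrees.  Sampling is overdamped Langevin dynamics run
directly in CV space on an analytic potential — the well-tempered
bias logic (Gaussian hills of width w, initial height h0, heights
decaying as exp(-V_bias/kBdT)) is the modelled protocol; the
molecular sampler of an all-atom simulation is not reproduced.

Free energies are in kcal/mol throughout; the free-energy estimator is

    F(s) = -(kB*T + kBdT)/kBdT * V_bias(s),

gauge-fixed so that min F = 0.  The conventional dimensionless bias
factor is gamma = 1 + kBdT/(kB*T) (~34.6 for kBdT = 20 kcal/mol at
300 K).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KB_KCAL",
    "WTMetaDParams",
    "BiasPotential",
    "FESGrid",
    "deposit_hill",
    "run_wtmetad",
    "reconstruct_fes",
    "find_minima",
    "prominent_minima",
    "barrier_between",
    "write_hills",
    "read_hills",
]

#: Boltzmann constant in kcal mol^-1 K^-1.
KB_KCAL = 1.98720425e-3


def wrap_angle(x):
    """Wrap angle(s) in degrees to the half-open interval [-180, 180)."""
    return (np.asarray(x, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class WTMetaDParams:
    """Well-tempered metadynamics and Langevin integration parameters.

    hill_width : Gaussian sigma per CV in degrees (default 5.0).
    h0 : initial hill height, kcal/mol (default 0.1).
    deposit_interval : engine time between hill depositions.
    kb_delta_t : well-tempering energy kB*dT, kcal/mol (default 20).
    temperature : K.  friction, dt : overdamped-Langevin parameters in
    reduced engine time units.
    """

    hill_width: float = 5.0
    h0: float = 0.1
    deposit_interval: float = 0.5
    kb_delta_t: float = 20.0
    temperature: float = 300.0
    friction: float = 0.05
    dt: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hill_width", "h0", "deposit_interval", "kb_delta_t", "temperature", "friction", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dt > self.deposit_interval:
            raise ValueError("dt must not exceed deposit_interval")

    @property
    def bias_factor(self) -> float:
        """Dimensionless well-tempering factor gamma = 1 + kBdT/(kB T)."""
        return 1.0 + self.kb_delta_t / (KB_KCAL * self.temperature)


class BiasPotential:
    """Accumulated Gaussian hill bias over the periodic CV plane.

    Hills are stored as (time, center_cv1, center_cv2, height); widths
    are constant per run.  Angular distances use the minimum image on
    the 360-degree torus, so translating any hill center by 360 degrees
    leaves the bias unchanged to machine precision.
    """

    def __init__(self, width_cv1: float, width_cv2: float | None = None):
        if width_cv2 is None:
            width_cv2 = width_cv1
        if width_cv1 <= 0 or width_cv2 <= 0:
            raise ValueError("hill widths must be positive")
        self.widths = (float(width_cv1), float(width_cv2))
        self.times: list[float] = []
        self._centers: list[tuple[float, float]] = []
        self._heights: list[float] = []
        self._cache: tuple[np.ndarray, np.ndarray] | None = None

    def __len__(self) -> int:
        return len(self._heights)

    def _arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if self._cache is None or self._cache[1].size != len(self._heights):
            self._cache = (
                np.asarray(self._centers).reshape(-1, 2),
                np.asarray(self._heights),
            )
        return self._cache

    @property
    def centers(self) -> np.ndarray:
        return self._arrays()[0]

    @property
    def heights(self) -> np.ndarray:
        return self._arrays()[1]

    def add_hill(self, time: float, cv1: float, cv2: float, height: float) -> None:
        if height <= 0:
            raise ValueError("hill height must be positive")
        self.times.append(float(time))
        self._centers.append((float(wrap_angle(cv1)), float(wrap_angle(cv2))))
        self._heights.append(float(height))
        self._cache = None

    def value(self, cv1, cv2) -> np.ndarray | float:
        """Bias energy (kcal/mol) at CV point(s); broadcasting over inputs."""
        cv1 = np.asarray(cv1, dtype=float)
        cv2 = np.asarray(cv2, dtype=float)
        if len(self) == 0:
            out = np.zeros(np.broadcast(cv1, cv2).shape)
            return float(out) if out.ndim == 0 else out
        w1, w2 = self.widths
        call_c, all_h = self._arrays()
        out = np.zeros(np.broadcast(cv1, cv2).shape)
        # chunk over hills so broadcast temporaries stay small
        chunk = max(1, int(5e7 // max(out.size, 1)))
        for k in range(0, len(self), chunk):
            c = call_c[k : k + chunk]
            h = all_h[k : k + chunk]
            d1 = wrap_angle(cv1[..., None] - c[:, 0])
            d2 = wrap_angle(cv2[..., None] - c[:, 1])
            out = out + (h * np.exp(-(d1**2) / (2 * w1**2) - (d2**2) / (2 * w2**2))).sum(axis=-1)
        return float(out) if out.ndim == 0 else out

    def value_on_grid(self, ax1: np.ndarray, ax2: np.ndarray) -> np.ndarray:
        """Bias on the outer product of two CV axes, (len(ax1), len(ax2)).

        Uses the per-axis separability of the Gaussian hills, so the
        cost is two (n_axis x n_hills) tables and one matmul.
        """
        if len(self) == 0:
            return np.zeros((len(ax1), len(ax2)))
        w1, w2 = self.widths
        c, h = self._arrays()
        a = np.exp(-(wrap_angle(np.asarray(ax1)[:, None] - c[:, 0]) ** 2) / (2 * w1**2))
        b = np.exp(-(wrap_angle(np.asarray(ax2)[:, None] - c[:, 1]) ** 2) / (2 * w2**2))
        return a @ (h[:, None] * b.T)

    def gradient(self, cv1: float, cv2: float) -> np.ndarray:
        """Analytic gradient (kcal/mol/degree) of the bias at one point."""
        if len(self) == 0:
            return np.zeros(2)
        w1, w2 = self.widths
        c, h = self._arrays()
        d1 = wrap_angle(cv1 - c[:, 0])
        d2 = wrap_angle(cv2 - c[:, 1])
        g = h * np.exp(-(d1**2) / (2 * w1**2) - (d2**2) / (2 * w2**2))
        return np.array([-(d1 / w1**2) @ g, -(d2 / w2**2) @ g])


def deposit_hill(bias: BiasPotential, cv1: float, cv2: float, params: WTMetaDParams, time: float = 0.0) -> float:
    """Deposit one well-tempered hill at the current CV point.

    The height follows the well-tempering law
    h = h0 * exp(-V_bias(s)/kBdT) with the bias evaluated *before* the
    deposition; the first hill therefore has height exactly h0.
    Returns the deposited height.
    """
    v = bias.value(cv1, cv2)
    h = params.h0 * float(np.exp(-v / params.kb_delta_t))
    bias.add_hill(time, cv1, cv2, h)
    return h


class _BiasGridCache:
    """Bias value/gradient tabulated on a periodic grid for O(1) lookups.

    Each deposited hill adds its analytic value and gradient on a local
    patch (out to 5 sigma); lookups use periodic bilinear interpolation.
    With hill widths of several degrees and ~1-2 degree spacing the
    interpolation error is far below the hill granularity of the bias.
    """

    def __init__(self, widths: tuple[float, float], spacing: float):
        self.widths = widths
        self.n = int(round(360.0 / spacing))
        self.spacing = 360.0 / self.n
        self.ax = -180.0 + self.spacing * np.arange(self.n)
        self.v = np.zeros((self.n, self.n))
        self.gx = np.zeros((self.n, self.n))
        self.gy = np.zeros((self.n, self.n))

    def add(self, c1: float, c2: float, h: float) -> None:
        w1, w2 = self.widths
        r1 = int(np.ceil(5.0 * w1 / self.spacing))
        r2 = int(np.ceil(5.0 * w2 / self.spacing))
        i0 = int(np.floor((c1 + 180.0) / self.spacing))
        j0 = int(np.floor((c2 + 180.0) / self.spacing))
        ii = (i0 + np.arange(-r1, r1 + 1)) % self.n
        jj = (j0 + np.arange(-r2, r2 + 1)) % self.n
        d1 = wrap_angle(self.ax[ii] - c1)[:, None]
        d2 = wrap_angle(self.ax[jj] - c2)[None, :]
        g = h * np.exp(-(d1**2) / (2 * w1**2) - (d2**2) / (2 * w2**2))
        self.v[np.ix_(ii, jj)] += g
        self.gx[np.ix_(ii, jj)] += -(d1 / w1**2) * g
        self.gy[np.ix_(ii, jj)] += -(d2 / w2**2) * g

    def _bilinear(self, table: np.ndarray, x: float, y: float) -> float:
        fx = (x + 180.0) / self.spacing
        fy = (y + 180.0) / self.spacing
        i = int(np.floor(fx)) % self.n
        j = int(np.floor(fy)) % self.n
        tx = fx - np.floor(fx)
        ty = fy - np.floor(fy)
        i1 = (i + 1) % self.n
        j1 = (j + 1) % self.n
        return (
            table[i, j] * (1 - tx) * (1 - ty)
            + table[i1, j] * tx * (1 - ty)
            + table[i, j1] * (1 - tx) * ty
            + table[i1, j1] * tx * ty
        )

    def value(self, x: float, y: float) -> float:
        return float(self._bilinear(self.v, x, y))

    def gradient(self, x: float, y: float) -> np.ndarray:
        return np.array([self._bilinear(self.gx, x, y), self._bilinear(self.gy, x, y)])


def run_wtmetad(
    potential,
    gradient,
    params: WTMetaDParams,
    n_steps: int,
    x0=(0.0, 0.0),
    cache_spacing: float | None = 1.5,
) -> tuple[np.ndarray, BiasPotential]:
    """Run overdamped Langevin dynamics with well-tempered hill deposition.

    Parameters
    ----------
    potential, gradient : callables
        ``potential(cv1, cv2) -> kcal/mol`` (periodic in both CVs) and
        its analytic gradient ``gradient(cv1, cv2) -> (2,)``.
    params : WTMetaDParams
    n_steps : number of dt-steps.
    x0 : starting CV point, degrees.

    Returns the trajectory (n_steps + 1, 2) and the accumulated bias.
    The update is s <- s + dt*(-grad(U + V_bias))/friction + noise with
    noise variance 2 kB T dt / friction, wrapped per CV.

    ``cache_spacing`` enables a grid-tabulated bias for the dynamics
    (periodic bilinear interpolation; hills still recorded exactly);
    pass None to evaluate the exact Gaussian sum at every step instead
    (slower, identical physics up to the interpolation error).
    """
    rng = np.random.default_rng(params.seed)
    bias = BiasPotential(params.hill_width)
    cache = _BiasGridCache(bias.widths, cache_spacing) if cache_spacing else None
    x = wrap_angle(np.asarray(x0, dtype=float)).copy()
    traj = np.empty((n_steps + 1, 2))
    traj[0] = x
    sigma = np.sqrt(2.0 * KB_KCAL * params.temperature * params.dt / params.friction)
    steps_per_hill = max(1, int(round(params.deposit_interval / params.dt)))
    for step in range(1, n_steps + 1):
        vgrad = cache.gradient(x[0], x[1]) if cache else bias.gradient(x[0], x[1])
        force = -(np.asarray(gradient(x[0], x[1]), dtype=float) + vgrad)
        dx = params.dt * force / params.friction + sigma * rng.standard_normal(2)
        if np.any(np.abs(dx) > 90.0):
            raise RuntimeError(
                f"unstable step |dx| = {np.max(np.abs(dx)):.1f} deg at step {step}; reduce dt"
            )
        x = wrap_angle(x + dx)
        traj[step] = x
        if step % steps_per_hill == 0:
            if cache:
                v = cache.value(x[0], x[1])
                h = params.h0 * float(np.exp(-v / params.kb_delta_t))
                bias.add_hill(step * params.dt, x[0], x[1], h)
                cache.add(float(x[0]), float(x[1]), h)
            else:
                deposit_hill(bias, x[0], x[1], params, time=step * params.dt)
    return traj, bias


@dataclass(frozen=True)
class FESGrid:
    """Free-energy surface on a regular periodic grid over [-180, 180)^2.

    ``cv1`` and ``cv2`` are the 1-D grid axes (degrees); ``values`` is
    (len(cv1), len(cv2)) in kcal/mol, gauge-fixed to min = 0 when built
    by :func:`reconstruct_fes`.
    """

    cv1: np.ndarray
    cv2: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cv1 = np.asarray(self.cv1, dtype=float)
        cv2 = np.asarray(self.cv2, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if values.shape != (cv1.size, cv2.size):
            raise ValueError("values must be (len(cv1), len(cv2))")
        if not np.all(np.isfinite(values)):
            raise ValueError("free energies must be finite")
        object.__setattr__(self, "cv1", cv1)
        object.__setattr__(self, "cv2", cv2)
        object.__setattr__(self, "values", values)


def grid_axes(spacing: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Regular axes over [-180, 180) at the given spacing in degrees."""
    n = int(round(360.0 / spacing))
    ax = -180.0 + spacing * np.arange(n)
    return ax, ax.copy()


def reconstruct_fes(bias: BiasPotential, params: WTMetaDParams, spacing: float = 1.0) -> FESGrid:
    """Well-tempered free-energy estimate from the accumulated bias."""
    if len(bias) == 0:
        raise ValueError("cannot reconstruct a free-energy surface from an empty bias")
    ax1, ax2 = grid_axes(spacing)
    scale = (KB_KCAL * params.temperature + params.kb_delta_t) / params.kb_delta_t
    v = bias.value_on_grid(ax1, ax2)
    f = -scale * v
    f -= f.min()
    return FESGrid(ax1, ax2, f, meta={"bias_factor": params.bias_factor, "n_hills": len(bias)})


def _neighbors(i: int, j: int, n1: int, n2: int):
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            yield (i + di) % n1, (j + dj) % n2


def find_minima(f: FESGrid, refine: bool = True) -> list[tuple[float, float, float]]:
    """Local minima of the periodic surface, sorted by free energy.

    A grid point is a minimum when it lies below all 8 periodic
    neighbours; the location is refined by a quadratic fit along each
    axis (sub-grid precision) when ``refine`` is set.
    """
    v = f.values
    n1, n2 = v.shape
    shifted = [np.roll(np.roll(v, di, axis=0), dj, axis=1)
               for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    is_min = np.all([v < s for s in shifted], axis=0)
    out = []
    d1 = f.cv1[1] - f.cv1[0]
    d2 = f.cv2[1] - f.cv2[0]
    for i, j in zip(*np.nonzero(is_min)):
        c1, c2, val = f.cv1[i], f.cv2[j], v[i, j]
        if refine:
            # 1-D parabola through the three axis-aligned points per CV.
            vm, vp = v[(i - 1) % n1, j], v[(i + 1) % n1, j]
            denom = vm - 2 * val + vp
            if denom > 0:
                c1 = c1 + 0.5 * (vm - vp) / denom * d1
            vm, vp = v[i, (j - 1) % n2], v[i, (j + 1) % n2]
            denom = vm - 2 * val + vp
            if denom > 0:
                c2 = c2 + 0.5 * (vm - vp) / denom * d2
        out.append((float(wrap_angle(c1)), float(wrap_angle(c2)), float(val)))
    return sorted(out, key=lambda m: m[2])


def _bottleneck_to_set(v: np.ndarray, start: tuple[int, int], targets: set[tuple[int, int]]) -> float:
    """Lowest possible path ceiling from ``start`` to any node in ``targets``."""
    n1, n2 = v.shape
    best = np.full((n1, n2), np.inf)
    best[start] = v[start]
    heap = [(v[start], start)]
    while heap:
        ceil, (i, j) = heapq.heappop(heap)
        if (i, j) in targets:
            return float(ceil)
        if ceil > best[i, j]:
            continue
        for ni, nj in _neighbors(i, j, n1, n2):
            cand = max(ceil, v[ni, nj])
            if cand < best[ni, nj]:
                best[ni, nj] = cand
                heapq.heappush(heap, (cand, (ni, nj)))
    return float("inf")


def prominent_minima(f: FESGrid, min_prominence: float) -> list[tuple[float, float, float]]:
    """Minima with topographic prominence of at least ``min_prominence``.

    The prominence of a minimum is the height of the lowest saddle
    separating it from any *deeper* minimum, relative to its own free
    energy; the global minimum is always kept.  Shallow ripple minima
    of a reconstructed surface (hill granularity) have prominence of
    the order of the bias roughness and are filtered out.
    """
    minima = find_minima(f, refine=False)
    if not minima:
        return []
    v = f.values
    nodes = [_nearest_node(f, m[:2]) for m in minima]
    kept = [minima[0]]
    for m, node in zip(minima[1:], nodes[1:]):
        deeper = {n for n, mm in zip(nodes, minima) if mm[2] < m[2]}
        saddle = _bottleneck_to_set(v, node, deeper)
        if saddle - m[2] >= min_prominence:
            kept.append(m)
    return kept


def _nearest_node(f: FESGrid, point) -> tuple[int, int]:
    i = int(np.argmin(np.abs(wrap_angle(f.cv1 - point[0]))))
    j = int(np.argmin(np.abs(wrap_angle(f.cv2 - point[1]))))
    return i, j


def barrier_between(f: FESGrid, a, b) -> float:
    """Lowest saddle separating two minima, relative to F(a).

    Computes the minimax path value (the smallest possible maximum free
    energy along any path) between the grid nodes nearest to ``a`` and
    ``b`` on the 8-connected periodic grid graph, and subtracts F(a).
    ``a`` and ``b`` must sit at (or within one cell of) local minima.
    """
    minima = find_minima(f, refine=False)
    d1 = abs(f.cv1[1] - f.cv1[0])
    for p in (a, b):
        if not any(
            abs(wrap_angle(p[0] - m[0])) <= 1.5 * d1 and abs(wrap_angle(p[1] - m[1])) <= 1.5 * d1
            for m in minima
        ):
            raise ValueError(f"point {tuple(p)} is not at a local minimum of the surface")
    v = f.values
    n1, n2 = v.shape
    start = _nearest_node(f, a)
    goal = _nearest_node(f, b)
    best = np.full((n1, n2), np.inf)
    h0 = max(v[start], v[goal])
    best[start] = max(v[start], h0)
    heap = [(best[start], start)]
    while heap:
        ceil, (i, j) = heapq.heappop(heap)
        if (i, j) == goal:
            return float(ceil - v[start[0], start[1]])
        if ceil > best[i, j]:
            continue
        for ni, nj in _neighbors(i, j, n1, n2):
            cand = max(ceil, v[ni, nj])
            if cand < best[ni, nj]:
                best[ni, nj] = cand
                heapq.heappush(heap, (cand, (ni, nj)))
    raise RuntimeError("unreachable: periodic grid graph is connected")


def write_hills(path, bias: BiasPotential, params: WTMetaDParams) -> None:
    """Write the hill log as a PLUMED-HILLS-style whitespace table."""
    with open(path, "w") as fh:
        fh.write("#! FIELDS time cv1 cv2 sigma_cv1 sigma_cv2 height biasf\n")
        w1, w2 = bias.widths
        bf = params.bias_factor
        for t, (c1, c2), h in zip(bias.times, bias.centers, bias.heights):
            fh.write(f"{t:.6f} {c1:.6f} {c2:.6f} {w1:.4f} {w2:.4f} {h:.10g} {bf:.4f}\n")


def read_hills(path) -> BiasPotential:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            rows.append([float(x) for x in line.split()])
    if not rows:
        raise ValueError(f"no hills found in {path}")
    arr = np.array(rows)
    bias = BiasPotential(arr[0, 3], arr[0, 4])
    for t, c1, c2, _, _, h, *_ in arr:
        bias.add_hill(t, c1, c2, h)
    return bias
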
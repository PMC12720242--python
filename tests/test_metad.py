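import numpy as np
import pytest

from ocphot import metad
from ocphot.metad import (
    BiasPotential,
    FESGrid,
    WTMetaDParams,
    barrier_between,
    deposit_hill,
    find_minima,
    read_hills,
    reconstruct_fes,
    run_wtmetad,
    wrap_angle,
    write_hills,
)
from ocphot.synthetic import ToyFES, make_toy_fes, three_well_preset


class TestBiasPotential:
    def test_empty_bias_is_zero(self):
        b = BiasPotential(5.0)
        assert b.value(10.0, -40.0) == 0.0
        np.testing.assert_array_equal(b.gradient(0.0, 0.0), [0.0, 0.0])

    def test_single_hill_center_value(self):
        b = BiasPotential(5.0)
        b.add_hill(0.0, 30.0, -60.0, 0.1)
        assert b.value(30.0, -60.0) == pytest.approx(0.1, rel=1e-14)

    def test_gradient_matches_central_differences(self):
        rng = np.random.default_rng(8)
        b = BiasPotential(7.0)
        for _ in range(30):
            b.add_hill(0.0, *rng.uniform(-180, 180, 2), rng.uniform(0.01, 0.1))
        h = 1e-5
        for _ in range(100):
            x, y = rng.uniform(-180, 180, 2)
            g = b.gradient(x, y)
            num = [
                (b.value(x + h, y) - b.value(x - h, y)) / (2 * h),
                (b.value(x, y + h) - b.value(x, y - h)) / (2 * h),
            ]
            np.testing.assert_allclose(g, num, atol=1e-6)

    def test_periodicity_under_center_translation(self):
        b1 = BiasPotential(5.0)
        b2 = BiasPotential(5.0)
        rng = np.random.default_rng(2)
        for _ in range(20):
            c1, c2 = rng.uniform(-180, 180, 2)
            h = rng.uniform(0.01, 0.1)
            b1.add_hill(0.0, c1, c2, h)
            b2.add_hill(0.0, c1 + 360.0, c2 - 360.0, h)
        pts = rng.uniform(-180, 180, (20, 2))
        for x, y in pts:
            assert b2.value(x, y) == pytest.approx(b1.value(x, y), abs=1e-14)

    def test_grid_evaluation_matches_pointwise(self):
        b = BiasPotential(6.0)
        rng = np.random.default_rng(12)
        for _ in range(25):
            b.add_hill(0.0, *rng.uniform(-180, 180, 2), rng.uniform(0.01, 0.1))
        ax1 = np.linspace(-180.0, 170.0, 12)
        ax2 = np.linspace(-180.0, 170.0, 9)
        grid = b.value_on_grid(ax1, ax2)
        for i in (0, 5, 11):
            for j in (0, 4, 8):
                assert grid[i, j] == pytest.approx(b.value(ax1[i], ax2[j]), rel=1e-12)


class TestWellTemperedDeposition:
    def test_first_hill_height_is_h0(self):
        params = WTMetaDParams()
        b = BiasPotential(params.hill_width)
        h = deposit_hill(b, 0.0, 0.0, params)
        assert h == 0.1  # exactly the configured initial height

    def test_height_at_bias_equal_kbdt(self):
        params = WTMetaDParams(kb_delta_t=20.0, h0=0.1)
        b = BiasPotential(params.hill_width)
        # stack hills until the bias at the origin reaches kbdt, then
        # verify the tempering factor directly
        b.add_hill(0.0, 0.0, 0.0, 20.0)
        h = deposit_hill(b, 0.0, 0.0, params)
        assert h == pytest.approx(0.1 / np.e, rel=1e-12)

    def test_fixed_point_recursion_oracle(self):
        # repeated deposition at one point follows the scalar recursion
        # V_{n+1} = V_n + h0 exp(-V_n / kbdt) exactly
        params = WTMetaDParams(h0=0.1, kb_delta_t=20.0)
        b = BiasPotential(params.hill_width)
        v_oracle = 0.0
        for _ in range(200):
            h = deposit_hill(b, 45.0, -45.0, params)
            assert h == pytest.approx(params.h0 * np.exp(-v_oracle / params.kb_delta_t), abs=1e-12)
            v_oracle += params.h0 * np.exp(-v_oracle / params.kb_delta_t)
        assert b.value(45.0, -45.0) == pytest.approx(v_oracle, abs=1e-10)

    def test_heights_nonincreasing_at_fixed_point(self):
        params = WTMetaDParams()
        b = BiasPotential(params.hill_width)
        hs = [deposit_hill(b, 10.0, 10.0, params) for _ in range(50)]
        assert all(h2 <= h1 for h1, h2 in zip(hs, hs[1:]))

    def test_bias_factor_value(self):
        # kbdt = 20 kcal/mol at 300 K: gamma = 1 + 20/(kB*300) ~ 34.5
        params = WTMetaDParams(kb_delta_t=20.0, temperature=300.0)
        assert params.bias_factor == pytest.approx(1.0 + 20.0 / (metad.KB_KCAL * 300.0))
        assert params.bias_factor == pytest.approx(34.55, abs=0.05)


class TestLangevinSampler:
    def test_zero_temperature_stays_at_minimum(self):
        fes = ToyFES([(0.0, 0.0, 5.0, 30.0)])
        params = WTMetaDParams(temperature=1e-9, dt=0.05, deposit_interval=1e6, friction=0.1, seed=0)
        traj, bias = run_wtmetad(fes, fes.gradient, params, 500, x0=(0.0, 0.0))
        assert np.all(np.abs(traj) < 1e-3)
        assert len(bias) == 0

    def test_deterministic_under_seed(self):
        fes = ToyFES([(0.0, 0.0, 2.0, 40.0)])
        params = WTMetaDParams(seed=42, dt=0.1, deposit_interval=1.0, friction=0.05)
        t1, b1 = run_wtmetad(fes, fes.gradient, params, 2000)
        t2, b2 = run_wtmetad(fes, fes.gradient, params, 2000)
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(b1.heights, b2.heights)
        np.testing.assert_array_equal(b1.centers, b2.centers)

    def test_flat_potential_uniform_histogram(self):
        flat = lambda x, y: 0.0
        gflat = lambda x, y: np.zeros(2)
        params = WTMetaDParams(seed=5, dt=0.5, deposit_interval=1e9, friction=0.005, temperature=300.0)
        traj, _ = run_wtmetad(flat, gflat, params, 80000, x0=(0.0, 0.0))
        counts, *_ = np.histogram2d(traj[:, 0], traj[:, 1], bins=4, range=[[-180, 180], [-180, 180]])
        n = traj.shape[0]
        p = 1.0 / 16.0
        # successive positions are correlated: the walk decorrelates over
        # a bin only after ~(bin/step)^2 steps, so the band uses the
        # effective (independent) sample size
        step_sd = np.sqrt(2 * metad.KB_KCAL * params.temperature * params.dt / params.friction)
        tau = (90.0 / step_sd) ** 2
        n_eff = n / tau
        sd = np.sqrt(n_eff * p * (1 - p)) / n_eff * n  # scale to raw counts
        assert np.all(np.abs(counts - n * p) < 3 * sd)

    def test_bias_enables_double_well_escape(self):
        fes = ToyFES([(-90.0, 0.0, 7.0, 30.0), (90.0, 0.0, 7.0, 30.0)], offset=7.0)
        base = dict(dt=0.1, friction=0.05, temperature=300.0, seed=7)
        no_bias = WTMetaDParams(deposit_interval=1e9, **base)
        traj0, _ = run_wtmetad(fes, fes.gradient, no_bias, 30000, x0=(-90.0, 0.0))
        assert (traj0[:, 0] > 0).mean() < 0.01  # trapped without bias
        biased = WTMetaDParams(deposit_interval=0.5, hill_width=8.0, h0=0.15, **base)
        traj1, _ = run_wtmetad(fes, fes.gradient, biased, 30000, x0=(-90.0, 0.0))
        assert (traj1[:, 0] > 0).mean() > 0.10
        assert (traj1[:, 0] < 0).mean() > 0.10

    def test_unstable_step_aborts_with_guidance(self):
        steep = ToyFES([(0.0, 0.0, 500.0, 10.0)])
        params = WTMetaDParams(dt=5.0, deposit_interval=5.0, friction=0.01, seed=0)
        with pytest.raises(RuntimeError, match="reduce dt"):
            run_wtmetad(steep, steep.gradient, params, 1000, x0=(15.0, 0.0))


class TestReconstruction:
    def test_single_hill_shape(self):
        params = WTMetaDParams(hill_width=10.0, h0=0.1)
        b = BiasPotential(10.0)
        b.add_hill(0.0, 0.0, 0.0, 0.1)
        f = reconstruct_fes(b, params, spacing=5.0)
        scale = (metad.KB_KCAL * 300.0 + 20.0) / 20.0
        # gauge-fixed negated hill: max depth = scale * height
        assert f.values.max() == pytest.approx(scale * 0.1, rel=1e-9)
        i, j = np.unravel_index(np.argmin(f.values), f.values.shape)
        assert (f.cv1[i], f.cv2[j]) == (0.0, 0.0)

    def test_height_scaling_is_linear(self):
        params = WTMetaDParams(hill_width=8.0)
        b1, b2 = BiasPotential(8.0), BiasPotential(8.0)
        rng = np.random.default_rng(1)
        for _ in range(20):
            c1, c2 = rng.uniform(-180, 180, 2)
            h = rng.uniform(0.01, 0.1)
            b1.add_hill(0.0, c1, c2, h)
            b2.add_hill(0.0, c1, c2, 2 * h)
        f1 = reconstruct_fes(b1, params, spacing=10.0)
        f2 = reconstruct_fes(b2, params, spacing=10.0)
        assert np.ptp(f2.values) == pytest.approx(2 * np.ptp(f1.values), rel=1e-10)

    def test_empty_bias_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_fes(BiasPotential(5.0), WTMetaDParams(), 5.0)

    def test_double_well_barrier_recovery(self):
        # 1D-like double well, flat second CV: reconstructed barrier
        # between the wells within 15% of the analytic value
        fes = ToyFES([(-90.0, 0.0, 4.0, 35.0), (90.0, 0.0, 4.0, 35.0)], offset=4.0)
        g = fes.grid(2.0)
        minima = find_minima(g)
        true_barrier = barrier_between(g, minima[0][:2], minima[1][:2])
        params = WTMetaDParams(hill_width=10.0, h0=0.02, deposit_interval=0.5,
                               dt=0.1, friction=0.02, seed=3)
        _, bias = run_wtmetad(fes, fes.gradient, params, 150000, x0=(-90.0, 0.0))
        rec = reconstruct_fes(bias, params, spacing=2.0)
        rec_minima = find_minima(rec)
        # the two deepest reconstructed minima are the wells
        a, b = rec_minima[0], rec_minima[1]
        rec_barrier = barrier_between(rec, a[:2], b[:2])
        assert rec_barrier == pytest.approx(true_barrier, rel=0.15)


class TestMinimaAndBarriers:
    def test_three_well_preset_minima(self):
        preset = three_well_preset()
        grid = preset.grid(1.0)
        minima = find_minima(grid)
        assert len(minima) == 3
        centers = {(-180.0, -180.0), (0.0, -180.0), (0.0, 0.0)}
        for c1, c2, _ in minima:
            assert any(
                abs(wrap_angle(c1 - a)) <= 1.0 and abs(wrap_angle(c2 - b)) <= 1.0
                for a, b in centers
            )

    def test_three_well_relative_energies_vs_dark(self):
        grid = three_well_preset().grid(1.0)
        minima = find_minima(grid)
        rel = sorted(m[2] - minima[0][2] for m in minima)
        assert rel[0] == 0.0
        assert rel[1] == pytest.approx(7.0, abs=1.5)
        assert rel[2] == pytest.approx(30.0, abs=1.5)

    def test_single_minimum_barrier_errors(self):
        fes, grid = make_toy_fes([(0.0, 0.0, 5.0, 30.0)])
        with pytest.raises(ValueError, match="minimum"):
            barrier_between(grid, (0.0, 0.0), (100.0, 100.0))

    def test_minimax_path_matches_exhaustive_enumeration(self):
        # coarse 12x12 periodic grid: compare against brute-force
        # minimax search over all simple paths (via repeated relaxation)
        rng = np.random.default_rng(0)
        vals = rng.uniform(0.0, 10.0, (12, 12))
        vals[2, 3] = -1.0
        vals[9, 8] = -0.5
        ax = -180.0 + 30.0 * np.arange(12)
        f = FESGrid(ax, ax.copy(), vals)

        # oracle: Floyd-Warshall-style minimax relaxation on the full graph
        n = 144
        big = np.full((n, n), np.inf)
        idx = lambda i, j: i * 12 + j
        for i in range(12):
            for j in range(12):
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == dj == 0:
                            continue
                        a, b = idx(i, j), idx((i + di) % 12, (j + dj) % 12)
                        big[a, b] = max(vals[i, j], vals[(i + di) % 12, (j + dj) % 12])
        dist = big.copy()
        np.fill_diagonal(dist, -np.inf)
        for k in range(n):
            dist = np.minimum(dist, np.maximum(dist[:, k : k + 1], dist[k : k + 1, :]))
        a, b = (2, 3), (9, 8)
        oracle = dist[idx(*a), idx(*b)] - vals[a]
        ours = barrier_between(f, (ax[2], ax[3]), (ax[9], ax[8]))
        assert ours == pytest.approx(max(oracle, 0.0), abs=1e-12)

    def test_subgrid_refinement_improves_location(self):
        fes, _ = make_toy_fes([(10.3, -20.7, 5.0, 30.0)])
        grid = fes.grid(2.0)
        (c1, c2, _), = find_minima(grid)
        assert c1 == pytest.approx(10.3, abs=0.3)
        assert c2 == pytest.approx(-20.7, abs=0.3)


def test_hills_file_round_trip(tmp_path):
    params = WTMetaDParams(hill_width=5.0)
    b = BiasPotential(5.0)
    rng = np.random.default_rng(3)
    for t in range(10):
        b.add_hill(float(t), *rng.uniform(-180, 180, 2), rng.uniform(0.01, 0.1))
    path = tmp_path / "run.hills"
    write_hills(path, b, params)
    back = read_hills(path)
    np.testing.assert_allclose(back.heights, b.heights, rtol=1e-9)
    np.testing.assert_allclose(back.centers, b.centers, atol=1e-5)
    assert back.widths == b.widths
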
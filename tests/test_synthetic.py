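import numpy as np
import pytest
from scipy.integrate import solve_ivp

from ocphot import synthetic
from ocphot.anisotropy import (
    PolarizedSpectra,
    anisotropy_from_magic_angle,
    average_anisotropy,
    raman_mask,
    tdm_angle_from_anisotropy,
)
from ocphot.kinetics import R_KCAL, svd_rank
from ocphot.spectra import Spectrum
from ocphot.synthetic import (
    IlluminationProtocol,
    RateTemperatureModel,
    VibronicSpeciesSpec,
    make_toy_fes,
    make_vibronic_spectrum,
    simulate_initial_rates,
    simulate_photoactivation_series,
    simulate_polarized_pair,
    three_well_preset,
)


class TestVibronicSpectrum:
    def test_zero_displacement_is_single_gaussian(self):
        spec = VibronicSpeciesSpec("x", origin=20000.0, s1=0.0, s2=0.0, linewidth=800.0)
        grid = np.arange(15000.0, 26000.0, 10.0)
        s = make_vibronic_spectrum(spec, grid)
        sigma = 800.0 / (2 * np.sqrt(2 * np.log(2)))
        expected = np.exp(-((grid - 20000.0) ** 2) / (2 * sigma**2))
        np.testing.assert_allclose(s.values, expected, atol=1e-12)

    def test_dominant_progression_spacing_is_cc_stretch(self):
        # narrow lines so peaks resolve; dominant spacing = 1517 cm^-1
        spec = VibronicSpeciesSpec("x", origin=20000.0, s1=1.0, s2=0.0, linewidth=300.0)
        grid = np.arange(18000.0, 27000.0, 1.0)
        s = make_vibronic_spectrum(spec, grid)
        v = s.values
        peaks = grid[1:-1][(v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])]
        spacings = np.diff(peaks[:3])
        np.testing.assert_allclose(spacings, 1517.0, atol=5.0)

    def test_integral_matches_quadrature_oracle(self):
        spec = VibronicSpeciesSpec("x", origin=19000.0, s1=0.8, s2=0.4, linewidth=500.0, amplitude=2.5)
        grid = np.arange(12000.0, 40000.0, 1.0)
        s = make_vibronic_spectrum(spec, grid)
        numeric = np.trapezoid(s.values, grid)
        sigma = 500.0 / (2 * np.sqrt(2 * np.log(2)))
        total_weight = sum(w for _, _, w in synthetic._fc_terms(spec))
        analytic = 2.5 * total_weight * sigma * np.sqrt(2 * np.pi)
        assert numeric == pytest.approx(analytic, rel=1e-6)
        assert 0.999 <= total_weight <= 1.0

    def test_nonnegative_everywhere(self):
        spec = VibronicSpeciesSpec("x", origin=20216.0)
        s = make_vibronic_spectrum(spec, synthetic.default_grid())
        assert np.all(s.values >= 0)

    def test_grid_validation(self):
        spec = VibronicSpeciesSpec("x", origin=20000.0)
        with pytest.raises(ValueError):
            make_vibronic_spectrum(spec, np.array([3.0, 2.0, 1.0]))
        with pytest.raises(ValueError):  # no overlap with the progression
            make_vibronic_spectrum(spec, np.array([100.0, 200.0]))

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            VibronicSpeciesSpec("x", origin=-5.0)
        with pytest.raises(ValueError):
            VibronicSpeciesSpec("x", origin=2e4, s1=-0.1)
        with pytest.raises(ValueError):
            VibronicSpeciesSpec("x", origin=2e4, linewidth=0.0)

    def test_ocpo_preset_puts_0_2_line_at_430_nm_marker(self):
        spec = synthetic.ocp_species_presets()["OCPO"]
        assert spec.origin + 2 * spec.mode1_freq == pytest.approx(23250.0)


class TestPhotoactivationSeries:
    def test_endpoints_are_reactant_and_product(self, species_basis):
        prot = IlluminationProtocol(
            excitation_wavenumber=22000.0, sample_times=(0.0, 1.0, 5000.0), noise_sd=0.0
        )
        ser = simulate_photoactivation_series(species_basis, 0.05, 0.01, prot)
        np.testing.assert_array_equal(ser.data[0], species_basis[0].values)
        # t >= 20/min(k1,k2): everything in the terminal compartment
        np.testing.assert_allclose(ser.data[-1], species_basis[2].values, atol=1e-6)

    def test_matches_ode_oracle(self, species_basis, two_scale_times):
        k1, k2 = 0.01, 0.002
        prot = IlluminationProtocol(excitation_wavenumber=2e4, sample_times=two_scale_times)
        ser = simulate_photoactivation_series(species_basis, k1, k2, prot)

        def rhs(_, y):
            return [-k1 * y[0], k1 * y[0] - k2 * y[1], k2 * y[1]]

        sol = solve_ivp(
            rhs, (0.0, two_scale_times[-1]), [1.0, 0.0, 0.0],
            t_eval=two_scale_times, rtol=1e-11, atol=1e-13,
        )
        bmat = np.vstack([b.values for b in species_basis])
        np.testing.assert_allclose(ser.data, sol.y.T @ bmat, atol=1e-8)

    def test_power_scales_rates(self, species_basis, two_scale_times):
        base = IlluminationProtocol(excitation_wavenumber=2e4, sample_times=two_scale_times)
        half = IlluminationProtocol(
            excitation_wavenumber=2e4, power=75.0, reference_power=150.0,
            sample_times=two_scale_times,
        )
        a = simulate_photoactivation_series(species_basis, 0.02, 0.004, half)
        b = simulate_photoactivation_series(species_basis, 0.01, 0.002, base)
        np.testing.assert_allclose(a.data, b.data, atol=1e-12)

    def test_seed_reproducibility(self, species_basis, two_scale_times):
        prot = IlluminationProtocol(
            excitation_wavenumber=2e4, sample_times=two_scale_times, noise_sd=0.01
        )
        a = simulate_photoactivation_series(species_basis, 0.01, 0.002, prot, seed=7)
        b = simulate_photoactivation_series(species_basis, 0.01, 0.002, prot, seed=7)
        np.testing.assert_array_equal(a.data, b.data)

    def test_noiseless_rank_exactly_three(self, species_basis, two_scale_times):
        prot = IlluminationProtocol(excitation_wavenumber=2e4, sample_times=two_scale_times)
        ser = simulate_photoactivation_series(species_basis, 0.01, 0.002, prot)
        n, s = svd_rank(ser)
        assert n == 3
        assert np.all(s[3:] < 1e-10 * s[0])

    def test_mismatched_grids_rejected(self, species_basis):
        bad = [species_basis[0], species_basis[1],
               Spectrum(species_basis[2].grid + 1.0, species_basis[2].values)]
        prot = IlluminationProtocol(excitation_wavenumber=2e4, sample_times=(0.0, 1.0))
        with pytest.raises(ValueError, match="grid"):
            simulate_photoactivation_series(bad, 0.01, 0.002, prot)
        with pytest.raises(ValueError):
            simulate_photoactivation_series(species_basis, -1.0, 0.002, prot)


class TestPolarizedPair:
    @staticmethod
    def emission_shape():
        grid = np.arange(15000.0, 23000.0, 10.0)
        return Spectrum(grid, np.exp(-((grid - 19000.0) ** 2) / (2 * 1200.0**2)), kind="emission")

    def test_theta_zero_gives_60_percent_perpendicular(self):
        i_ma, i_perp = simulate_polarized_pair(0.0, self.emission_shape())
        np.testing.assert_allclose(i_perp.values, 0.6 * i_ma.values, rtol=1e-12)

    def test_magic_angle_equalizes_polarizations(self):
        from ocphot.anisotropy import MAGIC_ANGLE_DEG

        i_ma, i_perp = simulate_polarized_pair(MAGIC_ANGLE_DEG, self.emission_shape())
        np.testing.assert_allclose(i_perp.values, i_ma.values, rtol=1e-12)

    def test_forward_inverse_round_trip_at_15_degrees(self):
        # a noiseless pair generated at theta = 15 deg inverts back exactly
        i_ma, i_perp = simulate_polarized_pair(15.0, self.emission_shape())
        pair = PolarizedSpectra(i_ma, i_perp, 23250.0)
        r = average_anisotropy(anisotropy_from_magic_angle(pair), window=(17000.0, 21000.0))
        assert r == pytest.approx(synthetic.anisotropy_from_angle(15.0), abs=1e-10)
        assert tdm_angle_from_anisotropy(r) == pytest.approx(15.0, abs=1e-9)

    @pytest.mark.parametrize("theta", [0.0, 10.0, 25.0, 40.0, 60.0])
    def test_angle_recovery_with_raman_masking(self, theta):
        lines = [(1517.0, 0.8, 40.0), (1157.0, 0.8, 40.0)]
        i_ma, i_perp = simulate_polarized_pair(
            theta, self.emission_shape(), raman_lines=lines, excitation_wavenumber=23250.0
        )
        pair = PolarizedSpectra(i_ma, i_perp, 23250.0)
        spec = anisotropy_from_magic_angle(pair)
        keep = raman_mask(spec.grid, 23250.0, (1517.0, 1157.0))
        r = average_anisotropy(spec, window=(18000.0, 21500.0), mask=keep)
        assert tdm_angle_from_anisotropy(r, mode="clamp") == pytest.approx(theta, abs=0.5)

    def test_theta_out_of_range(self):
        with pytest.raises(ValueError):
            simulate_polarized_pair(-1.0, self.emission_shape())


class TestInitialRates:
    def test_far_below_onset_is_negligible(self):
        model = RateTemperatureModel(prefactor=1.0, ea=8.5, t_on=240.0, onset_width=5.0)
        table = simulate_initial_rates(model, [150.0])
        arrhenius_alone = np.exp(-8.5 / (R_KCAL * 150.0))
        assert table["rate_per_s"].iloc[0] < 1e-6 * arrhenius_alone

    def test_pure_arrhenius_log_linear(self):
        model = RateTemperatureModel(prefactor=3.0, ea=8.5, t_on=1e-6, onset_width=1e-3)
        t = np.linspace(250.0, 320.0, 8)
        table = simulate_initial_rates(model, t, noise_frac=0.0)
        y = np.log(table["rate_per_s"].to_numpy())
        slope = np.polyfit(1.0 / t, y, 1)[0]
        assert -slope * R_KCAL == pytest.approx(8.5, rel=1e-6)

    def test_temperature_validation(self):
        with pytest.raises(ValueError):
            simulate_initial_rates(RateTemperatureModel(), [-10.0])


class TestToyFES:
    def test_single_minimum_at_center(self):
        fes, grid = make_toy_fes([(30.0, -60.0, 5.0, 25.0)])
        i, j = np.unravel_index(np.argmin(grid.values), grid.values.shape)
        assert grid.cv1[i] == pytest.approx(30.0, abs=1.0)
        assert grid.cv2[j] == pytest.approx(-60.0, abs=1.0)

    def test_periodicity_machine_precision(self):
        fes, _ = make_toy_fes([(10.0, 20.0, 4.0, 30.0)])
        pts = np.array([[-170.0, 5.0], [0.0, 0.0], [100.0, -150.0]])
        for cv1, cv2 in pts:
            assert fes(cv1 + 360.0, cv2) == pytest.approx(fes(cv1, cv2), abs=1e-12)
            assert fes(cv1, cv2 - 360.0) == pytest.approx(fes(cv1, cv2), abs=1e-12)

    def test_grid_consistent_with_callable(self):
        fes, grid = make_toy_fes([(0.0, 0.0, 3.0, 40.0)], offset=1.0)
        for i in (0, 50, 181):
            for j in (0, 90, 300):
                assert grid.values[i, j] == pytest.approx(fes(grid.cv1[i], grid.cv2[j]), abs=1e-12)

    def test_gradient_matches_finite_differences(self):
        fes, _ = make_toy_fes([(20.0, -40.0, 6.0, 30.0), (-100.0, 80.0, 3.0, 25.0)])
        rng = np.random.default_rng(4)
        h = 1e-5
        for _ in range(20):
            x, y = rng.uniform(-180, 180, 2)
            g = fes.gradient(x, y)
            num = [
                (fes(x + h, y) - fes(x - h, y)) / (2 * h),
                (fes(x, y + h) - fes(x, y - h)) / (2 * h),
            ]
            np.testing.assert_allclose(g, num, atol=1e-6)

    def test_three_well_relative_energies(self):
        preset = three_well_preset()
        dark = preset(-180.0, -180.0)
        p = preset(0.0, -180.0)
        q = preset(0.0, 0.0)
        assert p - dark == pytest.approx(30.0, abs=1.5)
        assert q - dark == pytest.approx(7.0, abs=1.5)

    def test_zero_minima_rejected(self):
        with pytest.raises(ValueError):
            make_toy_fes([])
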
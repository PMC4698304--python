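"""Four-layer corolla model: fit, predict, and pigment-distribution scenarios."""

import numpy as np
import pytest

from petaloptics import (
    KMParams,
    ScenarioSpec,
    Spectrum,
    build_flower_stack,
    build_scenario,
    fit_pigmented_layer,
    km_invert_rt,
    predict_spectra,
    saturation_metric,
    stack_spectra,
)
from petaloptics.errors import AlignmentError, FitDegenerateError, InvalidParameterError
from petaloptics.flower_model import FlowerConfig, KMLayer, SurfaceLayer
from petaloptics.kubelka_munk import PlateRT
from petaloptics.synthetic_data import make_pigment_kstar, simulate_measurement


class TestStackBuilding:
    def test_four_layers_with_printed_surface_values(self, grid, default_config, pigment_truth):
        K, S = pigment_truth
        stack = build_flower_stack(default_config, KMParams(K.values, S.values), grid)
        assert len(stack.layers) == 4
        assert isinstance(stack.layers[0], SurfaceLayer) and isinstance(stack.layers[3], SurfaceLayer)
        surf = stack.layers[0].plate()
        assert (surf.r_top, surf.t_down) == (0.03, 0.97)

    def test_zero_scattering_interior_collapses(self, grid, pigment_truth):
        """With S_u* = 0 the unpigmented layer is optically absent."""
        K, S = pigment_truth
        pigment = KMParams(K.values, S.values)
        with_layer = build_flower_stack(FlowerConfig(0.03, 0.0), pigment, grid)
        three = (SurfaceLayer(0.03), KMLayer(pigment), SurfaceLayer(0.03))
        from petaloptics.flower_model import StackModel
        without = StackModel(grid, three)
        for a, b in zip(stack_spectra(with_layer), stack_spectra(without)):
            np.testing.assert_allclose(a, b, atol=1e-14)

    def test_bare_plate_when_no_surface_no_interior(self, grid, pigment_truth):
        K, S = pigment_truth
        stack = build_flower_stack(FlowerConfig(0.0, 0.0), KMParams(K.values, S.values), grid)
        R, T, _ = stack_spectra(stack)
        from petaloptics.kubelka_munk import km_plate_rt
        bare = km_plate_rt(KMParams(K.values, S.values))
        np.testing.assert_allclose(R, bare.r_top, atol=1e-14)
        np.testing.assert_allclose(T, bare.t_down, atol=1e-14)


class TestFit:
    def test_noiseless_closure_recovers_truth(self, noiseless_measurement, default_config,
                                              pigment_truth, grid):
        R, T, _, _ = noiseless_measurement
        K, S = pigment_truth
        fit = fit_pigmented_layer(R, T, default_config)
        assert fit.n_valid == grid.size
        np.testing.assert_allclose(fit.K_p_star, K.values, atol=1e-6)
        np.testing.assert_allclose(fit.S_p_star, S.values, atol=1e-6)
        np.testing.assert_allclose(fit.D, np.log10(np.e) * K.values, atol=1e-6)
        i545 = int(np.argmin(np.abs(grid - 545.0)))
        assert fit.K_p_star[i545] == pytest.approx(1.4, abs=1e-6)

    def test_degenerate_config_equals_direct_inversion(self, grid, pigment_truth):
        """With no surfaces and no unpigmented layer, the fit is the bare inversion."""
        K, S = pigment_truth
        cfg = FlowerConfig(r_surface=0.0, S_u_star=0.0)
        stack = build_flower_stack(cfg, KMParams(K.values, S.values), grid)
        R, T, _, _ = simulate_measurement(stack, 0.0)
        fit = fit_pigmented_layer(R, T, cfg)
        direct = km_invert_rt(PlateRT(R.values, T.values))
        np.testing.assert_allclose(fit.K_p_star, direct.K_star, atol=1e-9)
        np.testing.assert_allclose(fit.S_p_star, direct.S_star, atol=1e-9)

    def test_unpigmented_scattering_shifts_sp_more_than_kp(self, noiseless_measurement):
        """Fitted K_p* barely depends on the assumed S_u*; S_p* absorbs it."""
        R, T, _, _ = noiseless_measurement
        f0 = fit_pigmented_layer(R, T, FlowerConfig(0.03, 0.0))
        f2 = fit_pigmented_layer(R, T, FlowerConfig(0.03, 0.2))
        rel_k = np.nanmean(np.abs(f0.K_p_star - f2.K_p_star)) / np.nanmean(f0.K_p_star)
        rel_s = np.nanmean(np.abs(f0.S_p_star - f2.S_p_star)) / np.nanmean(f0.S_p_star)
        assert rel_s > 2 * rel_k  # scattering absorbs the assumption
        assert np.nanmax(np.abs(f0.K_p_star - f2.K_p_star)) < 0.05 * np.nanmax(f0.K_p_star)
        assert rel_s > 0.1  # S_p* visibly differs

    def test_disjoint_wavelength_ranges_rejected(self):
        R = Spectrum(np.array([300.0, 400.0]), np.array([0.1, 0.1]), "reflectance")
        T = Spectrum(np.array([500.0, 600.0]), np.array([0.5, 0.5]), "transmittance")
        with pytest.raises(AlignmentError):
            fit_pigmented_layer(R, T)

    def test_all_invalid_raises_with_counts(self):
        wl = np.array([400.0, 500.0])
        R = Spectrum(wl, np.array([0.6, 0.7]), "reflectance")
        T = Spectrum(wl, np.array([0.5, 0.5]), "transmittance")  # R+T > 1 everywhere
        with pytest.raises(FitDegenerateError) as exc:
            fit_pigmented_layer(R, T)
        assert exc.value.failure_counts["energy"] == 2

    def test_mismatched_grids_are_aligned(self, default_config, pigment_truth):
        K, S = pigment_truth
        cfg = default_config
        grid = K.wavelengths
        stack = build_flower_stack(cfg, KMParams(K.values, S.values), grid)
        R, T, _, _ = simulate_measurement(stack, 0.0)
        # offset transmittance grid: forces internal resampling
        T_off = Spectrum(grid + 0.5, T.values, "transmittance")
        fit = fit_pigmented_layer(R, T_off, cfg)
        assert fit.n_valid > 0.9 * grid.size


class TestPredict:
    def test_round_trip_reproduces_inputs(self, noiseless_measurement, default_config):
        R, T, _, _ = noiseless_measurement
        fit = fit_pigmented_layer(R, T, default_config)
        R_ad, T_ad, R_ab, T_ab = predict_spectra(fit)
        np.testing.assert_allclose(R_ad.values, R.values, atol=1e-10)
        np.testing.assert_allclose(T_ad.values, T.values, atol=1e-10)

    def test_transmittance_identical_both_sides(self, noiseless_measurement, default_config):
        R, T, _, _ = noiseless_measurement
        fit = fit_pigmented_layer(R, T, default_config)
        _, T_ad, _, T_ab = predict_spectra(fit)
        np.testing.assert_array_equal(T_ad.values, T_ab.values)

    def test_homogeneous_assumption_reflects_adaxial_back(self, noiseless_measurement):
        """Fitting with S_u* = 0 treats the petal as one homogeneous layer, so
        the predicted abaxial reflectance equals the adaxial input."""
        R, T, _, _ = noiseless_measurement
        fit = fit_pigmented_layer(R, T, FlowerConfig(0.03, 0.0))
        _, _, R_ab, _ = predict_spectra(fit)
        np.testing.assert_allclose(R_ab.values, R.values, atol=1e-10)

    def test_abaxial_side_is_paler(self, noiseless_measurement, default_config, grid):
        """Pigment sits above the scattering layer, so the lower side reflects
        more at the absorption peak (less saturated colour)."""
        R, T, R_ab_true, _ = noiseless_measurement
        fit = fit_pigmented_layer(R, T, default_config)
        _, _, R_ab, _ = predict_spectra(fit)
        np.testing.assert_allclose(R_ab.values, R_ab_true.values, atol=1e-10)
        i545 = int(np.argmin(np.abs(grid - 545.0)))
        assert R_ab.values[i545] > R.values[i545]


@pytest.fixture(scope="module")
def pigment(grid):
    return make_pigment_kstar(grid=grid).values


class TestScenarios:
    def scenario_reflectances(self, grid, pigment, s_u=0.1):
        out = {}
        for tag in ("asymmetric", "homogeneous", "symmetric"):
            stack = build_scenario(ScenarioSpec(tag, pigment, 0.5, s_u, 0.03, wavelengths=grid))
            R_ad, T, R_ab = stack_spectra(stack)
            out[tag] = (R_ad, T, R_ab, stack)
        return out

    def test_budget_conserved_across_distributions(self, grid, pigment):
        runs = self.scenario_reflectances(grid, pigment)
        totals = {tag: (s.total_interior_kstar().sum(), s.total_interior_sstar().sum())
                  for tag, (_, _, _, s) in runs.items()}
        ref = totals["asymmetric"]
        for tK, tS in totals.values():
            assert tK == pytest.approx(ref[0], rel=1e-12)
            assert tS == pytest.approx(ref[1], rel=1e-12)

    def test_no_pigment_means_no_difference(self, grid):
        zero = np.zeros_like(grid)
        runs = self.scenario_reflectances(grid, zero)
        ref = runs["asymmetric"]
        for tag in ("homogeneous", "symmetric"):
            np.testing.assert_allclose(runs[tag][0], ref[0], atol=1e-12)
            np.testing.assert_allclose(runs[tag][1], ref[1], atol=1e-12)

    def test_asymmetric_most_saturated_adaxially(self, grid, pigment):
        runs = self.scenario_reflectances(grid, pigment)
        sats = {tag: saturation_metric(Spectrum(grid, R, "reflectance"), 545.0)
                for tag, (R, _, _, _) in runs.items()}
        assert sats["asymmetric"] > sats["homogeneous"]
        assert sats["asymmetric"] > sats["symmetric"]

    def test_homogeneous_close_to_symmetric(self, grid, pigment):
        runs = self.scenario_reflectances(grid, pigment)
        i545 = int(np.argmin(np.abs(grid - 545.0)))
        d_hs = abs(runs["homogeneous"][0][i545] - runs["symmetric"][0][i545])
        d_ah = abs(runs["asymmetric"][0][i545] - runs["homogeneous"][0][i545])
        assert d_hs < d_ah

    def test_unknown_distribution_rejected(self, grid):
        with pytest.raises(InvalidParameterError):
            ScenarioSpec("striped", np.zeros_like(grid))


class TestSaturationMetric:
    def test_flat_spectrum_zero(self):
        wl = np.arange(300.0, 701.0)
        assert saturation_metric(Spectrum(wl, np.full_like(wl, 0.4)), 545.0) == pytest.approx(0.0)

    def test_half_depth_trough(self):
        wl = np.arange(300.0, 701.0)
        vals = np.full_like(wl, 0.8)
        vals[wl == 545.0] = 0.4
        assert saturation_metric(Spectrum(wl, vals), 545.0) == pytest.approx(0.5)

    def test_out_of_range_peak_rejected(self):
        wl = np.arange(400.0, 501.0)
        with pytest.raises(AlignmentError):
            saturation_metric(Spectrum(wl, np.full_like(wl, 0.4)), 545.0)
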
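"""Workflow-level checks: calibration, diffusion-law classification,
chequerboard FCS, pair-correlation FCS and calibration-free iMSD."""

import math

import numpy as np
import pytest

from spadffs import (
    FfsSimConfig,
    InvalidInputError,
    acf_free3d,
    calibrate_waists,
    checkerboard_fcs,
    classify_diffusion_law,
    fit_acf,
    imsd,
    pair_correlation,
    rebin,
    simulate_ffs,
    spot_variation,
    sum_pixels,
    waist_from_tau_d,
)
from spadffs.correlate import chunked_correlate


class TestWaistArithmetic:
    def test_reference_conversion_values(self):
        # D = 90 um^2/s: tau_D = 94 us -> 184 nm, 132.3 us -> 218 nm
        assert waist_from_tau_d(90.0, 94e-6) * 1e3 == pytest.approx(184.0, abs=0.5)
        assert waist_from_tau_d(90.0, 132.3e-6) * 1e3 == pytest.approx(218.2, abs=0.5)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            waist_from_tau_d(90.0, 0.0)
        with pytest.raises(InvalidInputError):
            waist_from_tau_d(0.0, 1e-4)


class TestCalibration:
    def test_waists_ordered_and_center_near_truth(self, calibration_d90):
        w = calibration_d90.omega0_by_config
        assert w["center"] < w["sum3x3"] < w["sum5x5"]
        # the single-pixel volume should calibrate near the simulated waist
        assert w["center"] == pytest.approx(0.141, rel=0.10)

    def test_wrong_reference_d_scales_waists(self, trace_d90):
        cal = calibrate_waists(trace_d90, D_reference=45.0, chunk_length=2.0)
        w = cal.omega0_by_config["center"]
        assert w == pytest.approx(0.141 / math.sqrt(2), rel=0.10)

    def test_invalid_reference_rejected(self, trace_d90):
        with pytest.raises(InvalidInputError):
            calibrate_waists(trace_d90, D_reference=-1.0)


class TestDiffusionLawClassification:
    @pytest.mark.parametrize(
        "intercept_ms,stderr_ms,expected",
        [(0.1, 0.2, "free"), (1.0, 0.2, "microdomain"), (-1.0, 0.2, "meshwork")],
    )
    def test_verdicts(self, intercept_ms, stderr_ms, expected):
        assert classify_diffusion_law(intercept_ms * 1e-3, stderr_ms * 1e-3) == expected

    def test_threshold_is_tunable(self):
        assert classify_diffusion_law(1e-3, 0.4e-3, z=2.0) == "microdomain"
        assert classify_diffusion_law(1e-3, 0.4e-3, z=3.0) == "free"

    def test_zero_stderr_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_diffusion_law(1e-3, 0.0)


class TestSpotVariation:
    def test_free_diffusion_has_null_intercept_and_recovers_d(
        self, trace_d30, calibration_d90
    ):
        res = spot_variation(trace_d30, calibration_d90, fit_mode="none",
                             chunk_length=2.0)
        assert res.law == "free"
        assert abs(res.intercept) < 2.0 * res.intercept_stderr
        assert res.D_slope == pytest.approx(30.6, rel=0.2)
        for d_val in res.D_by_config.values():
            assert d_val == pytest.approx(30.6, rel=0.2)

    def test_pointwise_d_consistency(self, trace_d30, calibration_d90):
        res = spot_variation(trace_d30, calibration_d90, fit_mode="none",
                             chunk_length=2.0)
        for (w2, tD, (cfg, d_val)) in zip(res.omega0_sq, res.tau_D,
                                          res.D_by_config.items()):
            assert d_val == pytest.approx(w2 / (4 * tD), rel=1e-12)

    def test_tau_d_tracks_calibrated_waists(self, trace_d90, calibration_d90):
        """tau_D ratios across configurations match the omega0^2 ratios."""
        res = spot_variation(trace_d90, calibration_d90, fit_mode="none",
                             chunk_length=2.0)
        tau_ratio = res.tau_D / res.tau_D[0]
        w2_ratio = res.omega0_sq / res.omega0_sq[0]
        assert np.allclose(tau_ratio, w2_ratio, rtol=0.10)


class TestCheckerboard:
    def test_checker_ccf_has_no_short_lag_excess(self, trace_afterpulsing,
                                                 calibration_d90):
        fit, D, curve = checkerboard_fcs(trace_afterpulsing, calibration_d90,
                                         chunk_length=2.0)
        model = acf_free3d(curve.lags, fit.N, fit.tau_D, fit.S, fit.offset)
        short = curve.lags < 5e-6
        excess_ccf = np.mean((curve.G - model)[short])
        # same measurement, single-pixel ACF: after-pulsing dominates short lags
        acf = chunked_correlate(sum_pixels(trace_afterpulsing, "center"),
                                bin_width=trace_afterpulsing.bin_width,
                                chunk_length=2.0)
        f2 = fit_acf(acf, mode="crop", crop_min_lag=7.5e-6)
        model2 = acf_free3d(acf.lags, f2.N, f2.tau_D, f2.S, f2.offset)
        excess_acf = np.mean((acf.G - model2)[acf.lags < 5e-6])
        noise = np.mean(curve.G_std[short]) / math.sqrt(curve.n_chunks)
        assert abs(excess_ccf) < 4.0 * noise
        assert excess_acf > 10.0 * noise

    def test_after_pulse_free_simulation_d_matches_acf_d(self, trace_d30,
                                                         calibration_d90):
        fit, D, _ = checkerboard_fcs(trace_d30, calibration_d90, chunk_length=2.0)
        acf = chunked_correlate(sum_pixels(trace_d30, "sum5x5"),
                                bin_width=trace_d30.bin_width, chunk_length=2.0)
        f_acf = fit_acf(acf, mode="none")
        D_acf = calibration_d90.omega0_by_config["sum5x5"] ** 2 / (4 * f_acf.tau_D)
        assert D == pytest.approx(D_acf, rel=0.15)


class TestPairCorrelation:
    def test_global_fit_recovers_d(self, trace_d30):
        fit = pair_correlation(trace_d30, omega0=0.141, chunk_length=2.0)
        assert fit.D == pytest.approx(30.6, rel=0.15)

    def test_ideal_volumes_give_consistent_per_rho_fits(self, trace_d30):
        # equal Gaussian volumes everywhere: apparent D must not drift with rho
        fit = pair_correlation(trace_d30, omega0=0.141, chunk_length=2.0)
        ds = [fit.per_rho_D[r] for r in sorted(fit.per_rho_D)]
        assert len(ds) == 5
        for d_val in ds:
            assert d_val == pytest.approx(fit.D, rel=0.35)

    def test_missing_center_pixel_rejected(self, trace_d30):
        t = type(trace_d30)(counts=trace_d30.counts, bin_width=trace_d30.bin_width,
                            excluded_pixels=frozenset({12}))
        with pytest.raises(InvalidInputError):
            pair_correlation(t, omega0=0.141)


class TestImsd:
    @pytest.fixture(scope="class")
    def imsd_d90(self, trace_d90):
        return imsd(trace_d90, chunk_length=2.0)

    def test_recovers_d_within_twenty_percent(self, imsd_d90):
        fit, _, _ = imsd_d90
        assert fit.D == pytest.approx(90.0, rel=0.2)

    def test_intercept_is_half_waist_squared(self, imsd_d90):
        fit, _, _ = imsd_d90
        assert fit.intercept == pytest.approx(0.141**2 / 2, rel=0.35)

    def test_variance_increases_with_lag(self, imsd_d90):
        from scipy.stats import spearmanr

        fit, _, _ = imsd_d90
        # monotone trend within noise: strong rank correlation with lag
        rho, _ = spearmanr(fit.lags, fit.sigma2)
        assert rho > 0.9
        assert fit.sigma2[-1] > fit.sigma2[0]

    def test_gaussian_center_stays_at_zero_shift(self, imsd_d90):
        _, _, gfits = imsd_d90
        centers = [g.center for g in gfits if g is not None and g.valid]
        assert len(centers) >= 3
        for cx, cy in centers:
            assert abs(cx) < 0.2 and abs(cy) < 0.2

    def test_immobile_emitters_yield_no_spreading_signal(self):
        # a static emitter pattern has no concentration fluctuations, so no
        # significant correlation surface exists and the analysis says so
        xy = np.linspace(-0.3, 0.3, 5)
        gx, gy = np.meshgrid(xy, xy)
        pos = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(25)])
        cfg = FfsSimConfig(D=0.0, n_particles=25, brightness=2e5, duration=2.0,
                           bin_width=5e-6, dcr=0.0, hot_pixel_dcr=0.0,
                           p_afterpulse=0.0, init_positions=pos, seed=55)
        t = simulate_ffs(cfg)
        with pytest.raises(InvalidInputError, match="significant"):
            imsd(t, chunk_length=1.0, exclude_center_below=0.0)

    def test_quasi_static_diffusion_gives_near_zero_slope(self):
        # diffusion 180x slower than the fast reference: within the 800 us
        # window sigma^2 is nearly flat and D must come out consistent with
        # zero on the scale of the fast diffusant
        cfg = FfsSimConfig(D=0.5, n_particles=50, brightness=1e5, duration=4.0,
                           bin_width=5e-6, sim_substep=5e-6, dcr=0.0,
                           hot_pixel_dcr=0.0, p_afterpulse=0.0, seed=56)
        t = simulate_ffs(cfg)
        fit, _, _ = imsd(t, chunk_length=1.0)
        assert abs(fit.D) < 0.05 * 90.0

    def test_invariant_to_global_count_rescaling(self, trace_d90):
        fit1, _, _ = imsd(trace_d90, chunk_length=2.0)
        scaled = type(trace_d90)(counts=trace_d90.counts.astype(np.int64) * 3,
                                 bin_width=trace_d90.bin_width,
                                 excluded_pixels=trace_d90.excluded_pixels)
        fit2, _, _ = imsd(scaled, chunk_length=2.0)
        assert fit2.D == pytest.approx(fit1.D, rel=1e-6)


class TestCrossMethodConcordance:
    def test_all_four_estimators_agree_on_one_dataset(self, trace_d30,
                                                      calibration_d90):
        truth = 30.6
        sv = spot_variation(trace_d30, calibration_d90, fit_mode="none",
                            chunk_length=2.0)
        _, d_check, _ = checkerboard_fcs(trace_d30, calibration_d90,
                                         chunk_length=2.0)
        pc = pair_correlation(trace_d30,
                              omega0=calibration_d90.omega0_by_config["center"],
                              chunk_length=2.0)
        im, _, _ = imsd(rebin(trace_d30, 4), chunk_length=2.0)
        estimates = [sv.D_slope, d_check, pc.D, im.D]
        for est in estimates:
            assert est == pytest.approx(truth, rel=0.2)
        for a in estimates:
            for b in estimates:
                assert a == pytest.approx(b, rel=0.25)
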
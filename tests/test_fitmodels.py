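"""Analytic models, exact limits, and self-consistency of the fitters."""

import math

import numpy as np
import pytest

from spadffs import (
    InvalidInputError,
    acf_free3d,
    afterpulse_term,
    fit_acf,
    fit_afterpulse,
    fit_twofocus_global,
    gauss2d_fit,
    imsd_line_fit,
    twofocus_model,
)
from spadffs.correlate import CorrelationCurve, chunked_correlate, sum_pixels
from spadffs.fitmodels import gauss2d


def make_curve(lags, G, n_chunks=1, std=None):
    G = np.asarray(G, float)
    std = np.zeros_like(G) if std is None else np.asarray(std, float)
    return CorrelationCurve(np.asarray(lags, float), G, std, n_chunks, {})


def mt_like_lags(lo=1e-6, hi=0.1, n=64):
    return np.geomspace(lo, hi, n)


class TestModelFunctions:
    def test_free3d_amplitude_and_long_lag_limits(self):
        assert acf_free3d(1e-12, N=2.0, tau_D=1e-4, S=5.0, offset=0.3) == pytest.approx(0.8, rel=1e-6)
        assert acf_free3d(1e3, N=2.0, tau_D=1e-4, S=5.0, offset=0.3) == pytest.approx(0.3, rel=1e-4)

    def test_free3d_worked_value_at_tau_equals_tau_d(self):
        # (1/1) * (1/2) * (1 + 1/25)^(-1/2) = 0.5 / sqrt(1.04)
        v = acf_free3d(100e-6, N=1.0, tau_D=100e-6, S=5.0, offset=0.0)
        assert v == pytest.approx(0.5 / math.sqrt(1.04), abs=1e-12)
        assert v == pytest.approx(0.4902903, abs=1e-7)

    def test_models_positive_and_autocorrelations_monotone(self):
        tau = mt_like_lags()
        for f in (
            lambda t: acf_free3d(t, 0.5, 2e-4, 5.0, 0.0),
            lambda t: afterpulse_term(t, 1e-5, 1.103),
        ):
            v = f(tau)
            assert np.all(v > 0)
            assert np.all(np.diff(v) < 0)
        # the shifted-focus CCF is positive but peaks near the transit time,
        # so only positivity and eventual decay are required
        v = twofocus_model(tau, 0.5, 2e-4, 5.0, 0.141, 0.15)
        assert np.all(v > 0)
        assert np.argmax(v) < len(v) - 1 and v[-1] < 0.05 * v.max()

    def test_afterpulse_term_scaling(self):
        assert afterpulse_term(1e-5, A=0.0, B=1.103) == 0.0
        r = afterpulse_term(1e-5, 2.0, 1.103) / afterpulse_term(2e-5, 2.0, 1.103)
        assert r == pytest.approx(2**1.103, rel=1e-12)
        assert 2**1.103 == pytest.approx(2.148, abs=5e-4)
        with pytest.raises(InvalidInputError):
            afterpulse_term(1e-5, A=-1.0, B=1.103)

    def test_twofocus_reduces_to_acf_at_zero_shift(self):
        tau = mt_like_lags()
        a = twofocus_model(tau, 1.3, 1.6e-4, 5.0, 0.141, 0.0)
        b = acf_free3d(tau, 1.3, 1.6e-4, 5.0, 0.0)
        assert np.allclose(a, b, rtol=0, atol=0)

    def test_twofocus_shift_ratio_at_short_lag(self):
        # rho=2 vs rho=1 at tau->0: exp(-(4-1) d^2 / omega0^2)
        d, w = 0.075, 0.141
        tau = 1e-12
        r = (twofocus_model(tau, 1, 1e-4, 5, w, 2 * d)
             / twofocus_model(tau, 1, 1e-4, 5, w, d))
        assert r == pytest.approx(math.exp(-3 * d**2 / w**2), rel=1e-6)
        assert r == pytest.approx(0.4279, abs=2e-4)

    def test_twofocus_vanishes_at_long_lag_for_any_shift(self):
        # decay is algebraic (~tau^-3/2), so compare against the amplitude
        for shift in (0.0, 0.075, 0.3):
            amp = twofocus_model(1e-9, 1, 1e-4, 5, 0.141, 0.0)
            assert twofocus_model(10.0, 1, 1e-4, 5, 0.141, shift) < 1e-6 * amp


class TestAcfFit:
    def test_noiseless_self_consistency_to_six_digits(self):
        lags = mt_like_lags()
        G = acf_free3d(lags, N=2.0, tau_D=166e-6, S=5.0, offset=0.0)
        fit = fit_acf(make_curve(lags, G), mode="none", S_fixed=5.0)
        assert fit.N == pytest.approx(2.0, rel=1e-6)
        assert fit.tau_D == pytest.approx(166e-6, rel=1e-6)
        assert fit.valid

    def test_afterpulse_mode_recovers_both_components(self):
        lags = mt_like_lags()
        G = acf_free3d(lags, 1.5, 2e-4, 5.0, 0.0) + afterpulse_term(lags, 1e-6, 1.103)
        fit = fit_acf(make_curve(lags, G), mode="afterpulse", S_fixed=5.0)
        assert fit.tau_D == pytest.approx(2e-4, rel=1e-5)
        assert fit.A_ap == pytest.approx(1e-6, rel=1e-4)

    def test_crop_mode_drops_short_lags(self):
        lags = mt_like_lags()
        G = acf_free3d(lags, 1.0, 1e-4, 5.0, 0.0)
        # contamination sized to be dominant below the crop, negligible above
        G_dirty = G + afterpulse_term(lags, 2e-9, 1.103)
        fit = fit_acf(make_curve(lags, G_dirty), mode="crop", crop_min_lag=7.5e-6)
        assert fit.crop_min_lag == 7.5e-6
        assert fit.tau_D == pytest.approx(1e-4, rel=0.01)

    def test_too_few_points_rejected(self):
        lags = np.array([1e-6, 2e-6, 4e-6])
        with pytest.raises(InvalidInputError):
            fit_acf(make_curve(lags, np.ones(3)), mode="none")

    def test_crop_and_afterpulse_modes_agree_on_simulation(self, trace_afterpulsing):
        a = sum_pixels(trace_afterpulsing, "center")
        curve = chunked_correlate(a, bin_width=trace_afterpulsing.bin_width,
                                  chunk_length=2.0)
        f_crop = fit_acf(curve, mode="crop", crop_min_lag=7.5e-6)
        f_ap = fit_acf(curve, mode="afterpulse")
        se = math.hypot(f_crop.tau_D_stderr, f_ap.tau_D_stderr)
        assert abs(f_crop.tau_D - f_ap.tau_D) < max(2.0 * se, 0.15 * f_crop.tau_D)

    def test_diffusion_coefficient_conversion(self):
        lags = mt_like_lags()
        G = acf_free3d(lags, 1.0, 0.141**2 / (4 * 30.0), 5.0, 0.0)
        fit = fit_acf(make_curve(lags, G), mode="none")
        assert fit.diffusion_coefficient(0.141) == pytest.approx(30.0, rel=1e-5)


class TestAfterpulseFit:
    def test_exact_power_law_recovery(self):
        lags = mt_like_lags(1e-6, 1e-2)
        G = afterpulse_term(lags, 3e-6, 1.103)
        A, B, se = fit_afterpulse(make_curve(lags, G), (1e-6, 1e-2))
        assert B == pytest.approx(1.103, rel=1e-6)
        assert A == pytest.approx(3e-6, rel=1e-4)

    def test_window_too_small_rejected(self):
        lags = np.array([1e-6, 2e-6, 1e-3])
        with pytest.raises(InvalidInputError):
            fit_afterpulse(make_curve(lags, np.ones(3)), (1e-6, 1e-2))


class TestTwoFocusGlobalFit:
    RHOS = (1.0, math.sqrt(2), 2.0, math.sqrt(5), 2 * math.sqrt(2))

    def make_curves(self, D=32.5, omega0=0.141, d=0.075, N=0.8, noise=0.0, rng=None):
        tau_D = omega0**2 / (4 * D)
        out = {}
        for rho in self.RHOS:
            lags = mt_like_lags(1e-6, 1e-2)
            G = twofocus_model(lags, N, tau_D, 5.0, omega0, d * rho)
            if noise:
                G = G + rng.normal(0, noise, len(G))
            out[rho] = make_curve(lags, G)
        return out

    def test_noiseless_global_recovery_to_six_digits(self):
        curves = self.make_curves()
        fit = fit_twofocus_global(curves, omega0_fixed=0.141)
        assert fit.D == pytest.approx(32.5, rel=1e-6)
        assert fit.N == pytest.approx(0.8, rel=1e-6)

    def test_single_curve_global_equals_individual(self):
        curves = self.make_curves()
        one = {1.0: curves[1.0]}
        fit = fit_twofocus_global(one, omega0_fixed=0.141)
        assert fit.per_rho_tauD[1.0] == pytest.approx(fit.tau_D, rel=1e-9)

    def test_individual_fits_reported_per_class(self):
        fit = fit_twofocus_global(self.make_curves(), omega0_fixed=0.141)
        assert set(fit.per_rho_D) == set(self.RHOS)
        for d_val in fit.per_rho_D.values():
            assert d_val == pytest.approx(32.5, rel=1e-5)

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_twofocus_global({}, omega0_fixed=0.141)


class TestGauss2DFit:
    def test_exact_surface_recovery(self):
        xi, psi = np.meshgrid(np.arange(-4, 5), np.arange(-4, 5))
        mat = gauss2d((xi, psi), 0.1, 0.0, 0.0, 1.5, 0.002)
        fit = gauss2d_fit(mat)
        assert fit.sigma2 == pytest.approx(1.5, rel=1e-9)
        assert fit.amplitude == pytest.approx(0.1, rel=1e-9)
        assert fit.center == pytest.approx((0.0, 0.0), abs=1e-9)
        assert fit.valid

    def test_center_cell_exclusion_removes_spike_bias(self):
        xi, psi = np.meshgrid(np.arange(-4, 5), np.arange(-4, 5))
        mat = gauss2d((xi, psi), 0.1, 0.0, 0.0, 1.5, 0.0)
        mat[4, 4] += 5.0  # after-pulsing spike at zero shift
        fit = gauss2d_fit(mat, exclude_center=True)
        assert fit.sigma2 == pytest.approx(1.5, rel=1e-6)

    def test_flat_matrix_flagged(self):
        fit = gauss2d_fit(np.zeros((9, 9)))
        assert not fit.valid

    def test_shape_validation(self):
        with pytest.raises(InvalidInputError):
            gauss2d_fit(np.zeros((5, 5)))


class TestImsdLineFit:
    def test_exact_line_recovers_d_and_waist_intercept(self):
        lags = np.linspace(5e-6, 790e-6, 40)
        w0 = 0.141
        sigma2_um2 = 2 * 30.0 * lags + w0**2 / 2
        fit = imsd_line_fit(lags, sigma2_um2 / 0.075**2, max_lag=800e-6)
        assert fit.D == pytest.approx(30.0, rel=1e-9)
        assert fit.intercept == pytest.approx(w0**2 / 2, rel=1e-9)

    def test_zero_slope_gives_zero_d(self):
        lags = np.linspace(5e-6, 790e-6, 10)
        fit = imsd_line_fit(lags, np.full(10, 3.0), max_lag=800e-6)
        assert fit.D == pytest.approx(0.0, abs=1e-12)

    def test_lag_cap_applied(self):
        lags = np.array([1e-4, 2e-4, 4e-4, 6e-4, 5e-3])
        s2 = 2 * 10.0 * lags + 0.01
        s2[-1] += 99.0  # corrupt a lag above the cap; must be ignored
        fit = imsd_line_fit(lags, s2 / 0.075**2, max_lag=800e-6)
        assert fit.D == pytest.approx(10.0, rel=1e-9)
        assert fit.max_lag_used <= 800e-6

    def test_too_few_lags_rejected(self):
        with pytest.raises(InvalidInputError):
            imsd_line_fit([1e-4, 2e-4], [1.0, 2.0], max_lag=800e-6)
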
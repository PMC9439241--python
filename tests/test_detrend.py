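import numpy as np
import pytest
from dataclasses import replace

import hrvdecay as hd
from hrvdecay.detrend import (
    DetrendError,
    PolyDetrendConfig,
    detrend_poly,
    estimate_derivative,
    fit_ode,
    integrate_ode,
)
from hrvdecay.preprocess import RRSeries


class TestEstimateDerivative:
    def test_linear_function_exact(self):
        t = np.linspace(0.0, 10.0, 200)
        dy, ys = estimate_derivative(t, 3.0 * t + 5.0)
        np.testing.assert_allclose(dy, 3.0, atol=1e-8)
        np.testing.assert_allclose(ys, 3.0 * t + 5.0, atol=1e-8)

    def test_quadratic_derivative_analytic(self):
        t = np.linspace(0.0, 10.0, 400)
        dy, _ = estimate_derivative(t, t**2)
        interior = slice(20, -20)
        assert np.max(np.abs(dy[interior] - 2.0 * t[interior])) < 1e-6

    def test_noisy_sine_derivative(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0.0, 20.0, 2000)
        dy, _ = estimate_derivative(t, np.sin(t) + rng.normal(0.0, 0.01, t.size))
        interior = slice(100, -100)
        rms = np.sqrt(np.mean((dy[interior] - np.cos(t[interior])) ** 2))
        assert rms < 0.05

    def test_too_few_points(self):
        with pytest.raises(DetrendError):
            estimate_derivative(np.arange(5.0), np.arange(5.0))


class TestIntegrateODE:
    def test_equilibrium_is_a_fixed_point(self):
        c0, c1, c2, P = 20.0, -0.03, -0.06, 100.0
        eq = -(c0 + c2 * P) / c1
        t = np.arange(0.0, 200.0, 1.0)
        out = integrate_ode(c0, c1, c2, lambda tt: np.full(np.shape(tt), P), eq, t)
        np.testing.assert_allclose(out, eq, rtol=1e-12)

    def test_matches_closed_form_exponential(self):
        """Constant power from off-equilibrium: rr(t) = eq + (rr0-eq) e^{c1 t}."""
        c0, c1, c2, P, rr0 = 22.0, -1.0 / 40.0, -0.05, 150.0, 900.0
        eq = -(c0 + c2 * P) / c1
        t = np.arange(0.0, 600.0, 1.0)
        out = integrate_ode(c0, c1, c2, lambda tt: np.full(np.shape(tt), P), rr0, t)
        exact = eq + (rr0 - eq) * np.exp(c1 * t)
        np.testing.assert_allclose(out, exact, rtol=1e-6)

    def test_step_change_approaches_new_equilibrium(self):
        c0, c1, c2 = 20.0, -0.025, -0.05

        def power(tt):
            tt = np.asarray(tt, dtype=float)
            return np.where(tt < 300.0, 0.0, 100.0)

        t = np.arange(0.0, 1200.0, 1.0)
        out = integrate_ode(c0, c1, c2, power, -c0 / c1, t)
        eq2 = -(c0 + c2 * 100.0) / c1
        assert out[-1] == pytest.approx(eq2, rel=1e-4)
        # one time constant after the step: 63.2 % of the gap closed
        i = np.searchsorted(t, 300.0 - 1.0 / c1)
        gap = (-c0 / c1) - eq2
        assert out[i] == pytest.approx(eq2 + gap * np.exp(-1.0), rel=1e-2)


class TestFitODE:
    def test_noiseless_parameter_recovery(self, noiseless_subject):
        d = noiseless_subject
        fit = fit_ode(d.rr, d.protocol.power_at)
        assert fit.time_constant_s == pytest.approx(d.truth.ode_tau, rel=0.02)
        assert fit.gain_ms_per_w == pytest.approx(d.truth.ode_gain, rel=0.02)
        assert fit.baseline_ms == pytest.approx(d.truth.rr_rest, rel=0.02)
        assert fit.r2 > 0.999

    def test_detrending_is_exact_bookkeeping(self, subject):
        x_det, fit = hd.detrend_ode(subject.rr, subject.protocol.power_at)
        np.testing.assert_allclose(x_det + fit.trend_ms, subject.rr.rr_ms, rtol=0, atol=1e-9)

    def test_noiseless_detrend_residuals_below_one_ms(self, noiseless_subject):
        x_det, _ = hd.detrend_ode(noiseless_subject.rr, noiseless_subject.protocol.power_at)
        assert np.max(np.abs(x_det)) < 1.0

    def test_default_noise_parameter_recovery_bias(self):
        """Median relative bias of time constant and gain below 5 %."""
        truths = hd.draw_cohort_truths(12, seed=21)
        tc_rel, g_rel = [], []
        for i, tr in enumerate(truths):
            proto = hd.make_protocol(exhaustion_power_w=tr.exhaustion_power)
            d = hd.simulate_subject(proto, tr, seed=700 + i)
            fit = fit_ode(d.rr, d.protocol.power_at)
            tc_rel.append(abs(fit.time_constant_s / tr.ode_tau - 1.0))
            g_rel.append(abs(fit.gain_ms_per_w / tr.ode_gain - 1.0))
        assert np.median(tc_rel) < 0.05
        assert np.median(g_rel) < 0.05

    def test_constant_sigma_noise_recovered_in_residual_sd(self, noiseless_subject):
        d = noiseless_subject
        rng = np.random.default_rng(5)
        rr = RRSeries(d.rr.t_s, d.rr.rr_ms + rng.normal(0.0, 10.0, len(d.rr)), d.rr.phase)
        x_det, _ = hd.detrend_ode(rr, d.protocol.power_at)
        assert np.std(x_det, ddof=1) == pytest.approx(10.0, rel=0.05)

    def test_singular_regression_rejected(self):
        t = np.arange(0.0, 30.0, 0.6)
        rr = RRSeries(t, np.full(t.size, 600.0), np.full(t.size, "pre"))
        with pytest.raises(DetrendError):
            fit_ode(rr, lambda tt: np.zeros(np.shape(tt)))

    def test_median_r2_across_default_cohort(self):
        """ODE trend explains most RR variance on default synthetic tests."""
        cohort = hd.simulate_cohort(18, seed=31)
        r2 = []
        for d in cohort:
            _, fit, _ = hd.process_subject(d)
            r2.append(fit.r2)
        assert np.median(r2) >= 0.9


class TestPolyDetrend:
    @pytest.mark.parametrize("p", [0, 1, 2])
    @pytest.mark.parametrize("omega", [5, 21, 51])
    def test_annihilates_low_degree_trends(self, p, omega):
        i = np.arange(300.0)
        coeffs = [7.0, -0.3, 0.004][: p + 1]
        x = sum(c * i**k for k, c in enumerate(coeffs))
        resid = detrend_poly(x, PolyDetrendConfig(p, omega))
        assert np.max(np.abs(resid)) < 1e-9

    def test_order_zero_subtracts_window_mean(self):
        rng = np.random.default_rng(1)
        x = rng.normal(600.0, 20.0, 101)
        resid = detrend_poly(x, PolyDetrendConfig(0, 5))
        i = 50
        assert resid[i] == pytest.approx(x[i] - np.mean(x[i - 2:i + 3]), abs=1e-9)

    def test_linear_window_fit_matches_polyfit_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        resid = detrend_poly(x, PolyDetrendConfig(1, 5))
        u = np.arange(5.0)
        pred = np.polyval(np.polyfit(u, x, 1), 2.0)
        assert resid[2] == pytest.approx(x[2] - pred, abs=1e-9)

    def test_truncated_edges_still_annihilate_polynomials(self):
        i = np.arange(60.0)
        x = 5.0 + 0.2 * i
        resid = detrend_poly(x, PolyDetrendConfig(1, 21))
        assert np.max(np.abs(resid[:10])) < 1e-9
        assert np.max(np.abs(resid[-10:])) < 1e-9

    def test_series_shorter_than_window_rejected(self):
        with pytest.raises(DetrendError):
            detrend_poly(np.arange(10.0), PolyDetrendConfig(0, 21))

    @pytest.mark.parametrize("p, omega", [(3, 11), (0, 4), (2, 3)])
    def test_invalid_config_rejected(self, p, omega):
        with pytest.raises(DetrendError):
            PolyDetrendConfig(p, omega)
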
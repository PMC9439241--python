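import numpy as np
import pytest
from dataclasses import replace

import hrvdecay as hd
from hrvdecay.detrend import trend_at_beats
from hrvdecay.synthetic import GenerationError, _ode_coefficients


class TestSimulateSubject:
    def test_deterministic_under_seed(self, truths):
        tr = truths[0]
        proto = hd.make_protocol(exhaustion_power_w=tr.exhaustion_power)
        a = hd.simulate_subject(proto, tr, seed=5)
        b = hd.simulate_subject(proto, tr, seed=5)
        np.testing.assert_array_equal(a.rr.rr_ms, b.rr.rr_ms)
        np.testing.assert_array_equal(a.rr.t_s, b.rr.t_s)
        c = hd.simulate_subject(proto, tr, seed=6)
        assert not np.array_equal(a.rr.rr_ms, c.rr.rr_ms)

    def test_beat_time_bookkeeping(self, subject):
        """t_{i+1} - t_i equals rr_i / 1000 for every emitted beat."""
        dt = np.diff(subject.rr.t_s)
        np.testing.assert_allclose(dt, subject.rr.rr_ms[:-1] / 1000.0, rtol=0, atol=1e-9)

    def test_noise_free_series_is_exactly_the_ode_trend(self, noiseless_subject):
        d = noiseless_subject
        c0, c1, c2 = _ode_coefficients(d.truth)
        trend = trend_at_beats(c0, c1, c2, d.protocol.power_at, d.truth.rr_rest, d.rr.t_s)
        assert np.max(np.abs(d.rr.rr_ms - trend)) < 1e-6

    def test_beat_count_matches_trend_quadrature(self, noiseless_subject):
        """Number of beats ~ integral of trend HR over the protocol, +-2."""
        d = noiseless_subject
        c0, c1, c2 = _ode_coefficients(d.truth)
        grid = np.arange(0.0, d.protocol.duration_s + 1.0, 1.0)
        from hrvdecay.detrend import integrate_ode

        trend = integrate_ode(c0, c1, c2, d.protocol.power_at, d.truth.rr_rest, grid)
        expected = np.trapezoid(1000.0 / trend, grid)
        assert abs(len(d.rr) - expected) <= 2.0

    def test_phases_follow_protocol(self, subject):
        spans = subject.protocol.phase_spans()
        assert set(subject.rr.phase) == {"pre", "effort", "recovery"}
        for ph, s, e in spans:
            sel = (subject.rr.t_s >= s) & (subject.rr.t_s < e)
            assert np.all(subject.rr.phase[sel] == ph)

    def test_excessive_gain_raises(self, truths):
        tr = replace(truths[0], ode_gain=truths[0].rr_rest / 50.0)
        proto = hd.make_protocol(exhaustion_power_w=tr.exhaustion_power)
        with pytest.raises(GenerationError):
            hd.simulate_subject(proto, tr, seed=1)

    def test_noise_law_recovered_from_windowed_sd(self, truths):
        """log2 windowed residual SD vs trend HR has slope -1/tau_true (5 %)."""
        tr = truths[1]
        proto = hd.make_protocol(exhaustion_power_w=tr.exhaustion_power)
        hr_all, sd_all = [], []
        for s in range(30):
            d = hd.simulate_subject(proto, tr, seed=3000 + s)
            resid = d.rr.rr_ms - d.trend_ms
            hr_trend = 60000.0 / d.trend_ms
            for lo in range(0, len(d.rr) - 60, 60):
                sd = np.std(resid[lo:lo + 60], ddof=1)
                if sd > 0:
                    hr_all.append(np.mean(hr_trend[lo:lo + 60]))
                    sd_all.append(sd)
        slope = np.polyfit(hr_all, np.log2(sd_all), 1)[0]
        assert slope == pytest.approx(-1.0 / tr.tau_true, rel=0.05)


class TestInjectArtifacts:
    def test_zero_rates_are_a_no_op(self, subject):
        out = hd.inject_artifacts(subject, hd.ArtifactSpec(0.0, 0.0, 0.0, seed=1))
        np.testing.assert_array_equal(out.rr.rr_ms, subject.rr.rr_ms)

    def test_exact_spike_count_and_shape(self, subject):
        rate = 3.0 / len(subject.rr)
        out = hd.inject_artifacts(subject, hd.ArtifactSpec(rate, 0.0, 0.0, seed=2))
        idx = out.artifact_idx["spike"]
        assert idx.size == 3
        assert np.all(out.rr.rr_ms[idx] > 1000.0)
        assert np.all(out.rr.phase[idx] == "effort")

    def test_calibration_rates_total_contamination(self, subject):
        out = hd.inject_artifacts(subject, hd.ArtifactSpec(seed=3))
        total = sum(v.size for v in out.artifact_idx.values())
        assert total / len(subject.rr) == pytest.approx(0.0054, abs=0.0015)

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(GenerationError):
            hd.ArtifactSpec(spike_rate=1.5)


class TestCohortGeneration:
    def test_perfect_negative_coupling_is_comonotone(self):
        for seed in range(5):
            truths = hd.draw_cohort_truths(10, coupling=-1.0, seed=seed)
            v = np.array([t.crf.vo2max for t in truths])
            tau = np.array([t.tau_true for t in truths])
            order = np.argsort(v)
            assert np.all(np.diff(tau[order]) < 0)

    def test_zero_coupling_uncorrelated_on_average(self):
        rs = []
        for seed in range(200):
            truths = hd.draw_cohort_truths(8, coupling=0.0, seed=seed)
            v = [t.crf.vo2max for t in truths]
            tau = [t.tau_true for t in truths]
            rs.append(hd.pearson_linear(tau, v)[0])
        assert abs(np.mean(rs)) < 0.05

    def test_b_true_loads_positively_on_fitness(self):
        truths = hd.draw_cohort_truths(60, coupling=-0.75, seed=4)
        r, p = hd.pearson_rank([t.b_true for t in truths],
                               [t.crf.vo2max for t in truths])
        assert r > 0.3 and p < 0.05

    def test_small_cohort_rejected(self):
        with pytest.raises(GenerationError):
            hd.draw_cohort_truths(2)

    def test_default_cohort_beat_counts_plausible(self):
        """Median beats per test inside the interquartile band [2433, 3548]."""
        cohort = hd.simulate_cohort(18, seed=12)
        counts = [len(d.rr) for d in cohort]
        assert 2433 <= np.median(counts) <= 3548

    def test_cohort_reproducible_and_artifact_ground_truth_recorded(self):
        a = hd.simulate_cohort(3, seed=8, artifacts=hd.ArtifactSpec())
        b = hd.simulate_cohort(3, seed=8, artifacts=hd.ArtifactSpec())
        for da, db in zip(a, b):
            np.testing.assert_array_equal(da.rr.rr_ms, db.rr.rr_ms)
            assert set(da.artifact_idx) == {"spike", "ratio", "jump"}

    def test_truth_invariants_enforced(self, truths):
        with pytest.raises(GenerationError):
            replace(truths[0], vo2_tau=truths[0].ode_tau + 1.0)
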
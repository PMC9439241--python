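import numpy as np
import pandas as pd
import pytest

import hrvdecay as hd
from hrvdecay.cohort import CohortError, compute_hrr, correlate_crf, crf_table
from hrvdecay.decay import fit_decay

from conftest import decay_windows


class TestPearsonLinear:
    @pytest.mark.parametrize("y_fn, expected", [
        (lambda x: 2 * x + 1, 1.0),
        (lambda x: -x, -1.0),
    ])
    def test_perfect_linearity(self, y_fn, expected):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = hd.pearson_linear(x, y_fn(x))
        assert r == pytest.approx(expected)

    def test_matches_product_moment_formula_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 3.0, 2.0, 4.0])
        r, p = hd.pearson_linear(x, y)
        xc, yc = x - x.mean(), y - y.mean()
        r_hand = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        t_hand = r_hand * np.sqrt((x.size - 2) / (1 - r_hand**2))
        from scipy import stats

        p_hand = 2 * stats.t.sf(abs(t_hand), x.size - 2)
        assert r == pytest.approx(r_hand, rel=1e-12)
        assert p == pytest.approx(p_hand, rel=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert hd.pearson_linear(x, y) == pytest.approx(hd.pearson_linear(y, x))

    def test_zero_variance_rejected(self):
        with pytest.raises(CohortError):
            hd.pearson_linear([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPearsonRank:
    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        r1, _ = hd.pearson_rank(x, np.exp(x))
        assert r1 == pytest.approx(1.0)
        r2, _ = hd.pearson_rank(x, x**3)
        assert r2 == pytest.approx(1.0)

    def test_reversed_order(self):
        x = np.arange(8.0)
        r, _ = hd.pearson_rank(x, x[::-1])
        assert r == pytest.approx(-1.0)

    def test_ties_match_midrank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0])
        y = np.array([4.0, 5.0, 6.0, 7.0])
        rx = np.array([1.0, 2.5, 2.5, 4.0])
        ry = np.array([1.0, 2.0, 3.0, 4.0])
        r, _ = hd.pearson_rank(x, y)
        assert r == pytest.approx(hd.pearson_linear(rx, ry)[0], rel=1e-12)


class TestHeartRateRecovery:
    def test_constant_hr_gives_zero(self):
        t = np.arange(0.0, 200.0, 0.5)
        assert compute_hrr(t, np.full(t.size, 150.0), exercise_end_s=100.0) == 0.0

    def test_matches_generator_trend_recovery(self, subject):
        """HRR from the beat series agrees with the ODE-trend ground truth."""
        end = next(e for ph, s, e in subject.protocol.phase_spans() if ph == "effort")
        hr_trend = 60000.0 / subject.trend_ms
        hrr = compute_hrr(subject.rr.t_s, hr_trend, exercise_end_s=end)
        assert hrr == pytest.approx(subject.crf.hrr, abs=2.0)

    def test_insufficient_recovery_rejected(self):
        t = np.arange(0.0, 100.0, 0.5)
        with pytest.raises(CohortError):
            compute_hrr(t, np.full(t.size, 150.0), exercise_end_s=70.0)


class TestFitCohort:
    def test_deterministic_and_recovers_subject_truth(self, small_cohort):
        fits1, tables = hd.fit_cohort(small_cohort)
        fits2, _ = hd.fit_cohort(small_cohort)
        assert [f.tau for f in fits1] == [f.tau for f in fits2]
        for f, d in zip(fits1, small_cohort):
            assert f.tau == pytest.approx(d.truth.tau_true, abs=3.0 * max(f.se_tau, 0.2))

    def test_window_counts_match_protocol_scale(self, small_cohort):
        _, tables = hd.fit_cohort(small_cohort)
        counts = [len(t) for t in tables]
        assert 18 <= np.median(counts) <= 26

    def test_too_few_subjects_rejected(self, small_cohort):
        with pytest.raises(CohortError):
            hd.fit_cohort(small_cohort[:2])


class TestCorrelateCRF:
    def _noise_free_fits(self, truths):
        """Fit each subject on windows drawn exactly from their decay law."""
        fits = []
        for t in truths:
            w = decay_windows(b=t.b_true, tau=t.tau_true,
                              hr=np.linspace(75.0, 185.0, 20))
            fits.append(fit_decay(w, model=1))
        return fits

    def test_comonotone_cohort_yields_rank_minus_one(self):
        truths = hd.draw_cohort_truths(10, coupling=-1.0, seed=3)
        fits = self._noise_free_fits(truths)
        crf = pd.DataFrame({
            "vo2max": [t.crf.vo2max for t in truths],
            "map": [t.crf.map_w for t in truths],
            "pvt1": [t.crf.pvt1_w for t in truths],
            "pvt2": [t.crf.pvt2_w for t in truths],
            "peak_hr": 187.0 + np.arange(10.0),
            "hrr": 30.0 + np.arange(10.0),
        })
        table = correlate_crf(fits, crf, method="rank")
        row = table[(table.coefficient == "tau_hr") & (table["index"] == "vo2max")]
        assert row.r.iloc[0] == pytest.approx(-1.0)

    def test_full_table_shape(self, small_cohort):
        fits, _ = hd.fit_cohort(small_cohort)
        table = correlate_crf(fits, crf_table(small_cohort), method="linear")
        assert len(table) == 12
        assert set(table.coefficient) == {"tau_hr", "b_hr"}
        assert np.all(table.r.abs() <= 1.0)
        assert np.all((table.p_value > 0) & (table.p_value <= 1.0))

    def test_mismatched_subjects_rejected(self, small_cohort):
        fits, _ = hd.fit_cohort(small_cohort)
        with pytest.raises(CohortError):
            correlate_crf(fits, crf_table(small_cohort).iloc[:3], method="linear")

    def test_negative_coupling_attenuated_but_negative(self):
        """Estimation noise shrinks |r| toward zero but keeps the sign."""
        rs = []
        for s in range(8):
            cohort = hd.simulate_cohort(8, coupling=-0.75, seed=200 + s, artifacts=None)
            fits, _ = hd.fit_cohort(cohort, clean=False)
            table = correlate_crf(fits, crf_table(cohort), method="linear")
            rs.append(table[(table.coefficient == "tau_hr")
                            & (table["index"] == "vo2max")].r.iloc[0])
        assert np.mean(rs) < 0.0


class TestSensitivityGrid:
    def test_restricted_grid_cardinality(self, small_cohort):
        grid = hd.sensitivity_grid(small_cohort[:3], omegas=[5], clean=False)
        assert len(grid) == 3
        assert set(grid.p) == {0, 1, 2}

    def test_grid_complete_and_reproducible(self, small_cohort):
        g1 = hd.sensitivity_grid(small_cohort[:3], orders=(0,), omegas=[31, 61],
                                 clean=False)
        g2 = hd.sensitivity_grid(small_cohort[:3], orders=(0,), omegas=[31, 61],
                                 clean=False)
        pd.testing.assert_frame_equal(g1, g2)
        assert list(g1.omega) == [31, 61]

    def test_zero_order_wide_window_detects_coupling(self):
        """Coarse mean-subtraction detrending with wide windows preserves a
        strong negative tau-fitness coupling (estimation noise attenuates
        the default-cohort coupling below reliable significance at n=18,
        so the qualitative pattern is checked on a strongly coupled cohort)."""
        cohort = hd.simulate_cohort(18, seed=77, coupling=-1.0, tau_sd=1.5)
        grid = hd.sensitivity_grid(cohort, orders=(0,), omegas=[61, 81, 101])
        assert np.all(grid.r < 0.0)
        assert grid.significant.mean() >= 0.5
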
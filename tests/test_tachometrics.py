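"""Unit and property tests for the tachometric analysis operations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from urgentrace import (
    binomial_ci,
    capture_range_accuracy,
    chronometric_curve,
    processing_time,
    rise_point,
    rise_point_ci,
    tachometric_curve,
)
from urgentrace.tachometrics import TachCurve

from _oracle import oracle_clopper_pearson, oracle_sliding_bins


def _table(pts, correct, gap=100.0):
    pts = np.asarray(pts, dtype=float)
    return pd.DataFrame(
        {
            "gap_ms": gap,
            "rt_ms": pts + gap,
            "pt_ms": pts,
            "correct": np.asarray(correct, dtype=bool),
            "valid": True,
        }
    )


class TestProcessingTime:
    @pytest.mark.parametrize(
        "rt,gap,expected", [(300, 150, 150), (200, 250, -50), (450, 25, 425)]
    )
    def test_direct_subtraction(self, rt, gap, expected):
        assert processing_time(rt, gap) == expected

    def test_missing_values_propagate(self):
        out = processing_time([300.0, np.nan], [100.0, 100.0])
        assert out[0] == 200.0 and np.isnan(out[1])


class TestBinomialCI:
    def test_boundaries(self):
        assert binomial_ci(0, 10)[0] == 0.0
        assert binomial_ci(10, 10)[1] == 1.0

    def test_undefined_for_empty(self):
        lo, hi = binomial_ci(0, 0)
        assert np.isnan(lo) and np.isnan(hi)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            binomial_ci(5, 3)

    def test_exhaustive_against_beta_quantile_oracle(self):
        """Exact Clopper-Pearson agreement for every (k, n) with n <= 50."""
        for n in range(1, 51):
            for k in range(n + 1):
                got = binomial_ci(k, n)
                want = oracle_clopper_pearson(k, n)
                assert got[0] == pytest.approx(want[0], abs=1e-9)
                assert got[1] == pytest.approx(want[1], abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(n=st.integers(1, 400), frac=st.floats(0, 1))
    def test_interval_brackets_point_estimate(self, n, frac):
        k = int(round(frac * n))
        lo, hi = binomial_ci(k, n)
        assert 0.0 <= lo <= k / n <= hi <= 1.0


class TestTachometricCurve:
    def test_all_correct_table_is_100_everywhere(self):
        t = _table(np.linspace(0, 200, 300), np.ones(300))
        curve = tachometric_curve(t)
        pop = curve.n_per_bin > 0
        assert np.all(curve.pct_correct[pop] == 100.0)
        assert np.all(curve.ci_high[pop] <= 100.0)

    def test_coin_flip_table_hovers_at_chance(self):
        rng = np.random.default_rng(0)
        n = 40_000
        t = _table(rng.uniform(0, 250, n), rng.random(n) < 0.5)
        curve = tachometric_curve(t)
        dense = curve.n_per_bin > 2000
        covers = (curve.ci_low[dense] < 50.0) & (curve.ci_high[dense] > 50.0)
        # individual 95% CIs miss ~5% of the time; demand the vast majority
        assert covers.mean() > 0.9
        assert np.abs(curve.pct_correct[dense] - 50.0).max() < 3.0

    def test_toy_table_matches_exhaustive_enumeration(self, toy_table):
        curve = tachometric_curve(toy_table)
        want = oracle_sliding_bins(
            toy_table["pt_ms"], toy_table["correct"], curve.pt_grid, 50.0
        )
        for i, (n, pct) in enumerate(want):
            assert curve.n_per_bin[i] == n
            if n:
                assert curve.pct_correct[i] == pytest.approx(pct)
            else:
                assert np.isnan(curve.pct_correct[i])

    def test_bin_membership_half_open(self):
        # bin [c-25, c+25): a trial at pt = c+25 is excluded, at c-25 included
        t = _table([75.0, 125.0], [1, 0])
        curve = tachometric_curve(t, grid_limits=(100, 100), step=1.0)
        i = np.where(curve.pt_grid == 100.0)[0][0]
        assert curve.n_per_bin[i] == 1  # only the 75 ms trial

    def test_step_5_agrees_with_step_1_at_shared_points(self, default_tables):
        t = default_tables["symmetric"]
        c1 = tachometric_curve(t, step=1.0)
        c5 = tachometric_curve(t, step=5.0)
        shared, i1, i5 = np.intersect1d(c1.pt_grid, c5.pt_grid, return_indices=True)
        assert len(shared) > 50
        np.testing.assert_array_equal(c1.n_per_bin[i1], c5.n_per_bin[i5])
        np.testing.assert_array_equal(c1.pct_correct[i1], c5.pct_correct[i5])

    def test_invariant_to_row_order_and_session_labels(self, default_tables):
        t = default_tables["congruent"].copy()
        shuffled = t.sample(frac=1.0, random_state=1).reset_index(drop=True)
        shuffled["session_id"] = np.arange(len(shuffled)) % 7
        c1, c2 = tachometric_curve(t), tachometric_curve(shuffled)
        np.testing.assert_array_equal(c1.pt_grid, c2.pt_grid)
        np.testing.assert_array_equal(c1.pct_correct, c2.pct_correct)
        np.testing.assert_array_equal(c1.n_per_bin, c2.n_per_bin)

    def test_ci_brackets_estimate_where_populated(self, default_tables):
        curve = tachometric_curve(default_tables["incongruent"])
        pop = curve.n_per_bin > 0
        assert np.all(curve.ci_low[pop] <= curve.pct_correct[pop] + 1e-12)
        assert np.all(curve.pct_correct[pop] <= curve.ci_high[pop] + 1e-12)
        assert np.all((curve.ci_low[pop] >= 0) & (curve.ci_high[pop] <= 100))

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            tachometric_curve(_table([], []))

    def test_invalid_trials_excluded_by_default(self):
        t = _table([100.0] * 10, [1] * 10)
        t.loc[5:, "valid"] = False
        curve = tachometric_curve(t, grid_limits=(100, 100))
        assert curve.n_per_bin[0] == 5
        curve_all = tachometric_curve(t, grid_limits=(100, 100), include_invalid=True)
        assert curve_all.n_per_bin[0] == 10


class TestCaptureRange:
    def test_all_correct_in_range(self):
        t = _table([80, 90, 100, 110, 120], [1, 1, 1, 1, 1])
        acc, (lo, hi) = capture_range_accuracy(t)
        assert acc == 100.0 and hi == 100.0

    def test_matches_direct_filter_oracle(self, default_tables):
        t = default_tables["incongruent"]
        acc, _ = capture_range_accuracy(t)
        v = t[t["valid"]]
        sel = v[(v["pt_ms"] >= 75) & (v["pt_ms"] <= 125)]
        assert acc == pytest.approx(100.0 * sel["correct"].mean())

    def test_range_is_inclusive(self):
        t = _table([75.0, 125.0, 74.999, 125.001], [1, 1, 0, 0])
        acc, _ = capture_range_accuracy(t)
        assert acc == 100.0

    def test_undefined_when_range_empty(self):
        t = _table([200.0, 300.0], [1, 1])
        acc, (lo, hi) = capture_range_accuracy(t)
        assert np.isnan(acc) and np.isnan(lo)


def _sigmoid_curve(x0=120.0, slope=0.1, lo=50.0, hi=100.0):
    grid = np.arange(0.0, 250.0, 1.0)
    pct = lo + (hi - lo) / (1.0 + np.exp(-slope * (grid - x0)))
    n = np.full(len(grid), 500)
    return TachCurve(grid, pct, pct - 1, pct + 1, n, 50.0), grid, pct


class TestRisePoint:
    def test_constant_100_returns_leftmost_point(self):
        grid = np.arange(50.0, 100.0)
        c = TachCurve(grid, np.full(50, 100.0), np.full(50, 95.0),
                      np.full(50, 100.0), np.full(50, 30), 50.0)
        assert rise_point(c) == 50.0

    def test_never_reaching_returns_nan(self):
        grid = np.arange(50.0, 100.0)
        c = TachCurve(grid, np.full(50, 60.0), np.full(50, 55.0),
                      np.full(50, 65.0), np.full(50, 30), 50.0)
        assert np.isnan(rise_point(c))

    def test_matches_analytic_sigmoid_crossing(self):
        curve, grid, pct = _sigmoid_curve()
        # analytic PT where the sigmoid reaches 75%: x0 + ln(1)/slope = x0
        analytic = 120.0
        assert rise_point(curve) == pytest.approx(analytic, abs=1.0)

    def test_interpolates_between_grid_points(self):
        grid = np.array([100.0, 110.0])
        c = TachCurve(grid, np.array([70.0, 80.0]), grid * 0, grid * 0 + 100,
                      np.array([30, 30]), 50.0)
        assert rise_point(c) == pytest.approx(105.0)


class TestRisePointCI:
    def test_deterministic_given_seed(self, toy_table):
        big = pd.concat([toy_table] * 30, ignore_index=True)
        a = rise_point_ci(big, n_boot=120, rng=5)
        b = rise_point_ci(big, n_boot=120, rng=5)
        assert a == b

    def test_interval_shrinks_with_sample_size(self):
        rng = np.random.default_rng(9)

        def step_table(n):
            pts = rng.uniform(0, 250, n)
            return _table(pts, pts > 120)  # noiseless step at 120 ms

        lo1, hi1, _ = rise_point_ci(step_table(400), n_boot=150, rng=1)
        lo2, hi2, _ = rise_point_ci(step_table(8000), n_boot=150, rng=1)
        assert (hi2 - lo2) < (hi1 - lo1)
        assert (hi2 - lo2) < 15.0

    def test_flagged_when_mostly_undefined(self):
        t = _table(np.linspace(0, 250, 60), np.zeros(60))  # never reaches 75%
        lo, hi, n_undef = rise_point_ci(t, n_boot=100, rng=2)
        assert np.isnan(lo) and np.isnan(hi)
        assert n_undef > 50

    def test_requires_minimum_resamples(self, toy_table):
        with pytest.raises(ValueError):
            rise_point_ci(toy_table, n_boot=10)

    def test_covers_reference_rise_point(self, params, default_tables):
        """The bootstrap interval covers the rise point of a larger
        reference simulation of the same process."""
        from urgentrace import TrialDesign, simulate_trials

        ref = simulate_trials(
            params, TrialDesign(proportions={"symmetric": 1.0}), 60_000,
            np.random.default_rng(100),
        )
        ref_rp = rise_point(tachometric_curve(ref))
        small = default_tables["symmetric"]
        lo, hi, _ = rise_point_ci(small, n_boot=200, rng=3)
        assert lo - 2.0 <= ref_rp <= hi + 2.0


class TestChronometricCurve:
    def test_single_gap_constant_rt_has_zero_sd(self):
        t = _table([50.0] * 5, [1] * 5, gap=100.0)
        c = chronometric_curve(t)
        assert len(c.gap) == 1 and c.sd_rt[0] == 0.0
        assert c.mean_rt[0] == 150.0

    def test_matches_hand_computation(self):
        t = pd.DataFrame(
            {
                "gap_ms": [25, 25, 50, 50, 50],
                "rt_ms": [200.0, 220.0, 300.0, 310.0, 320.0],
                "correct": True,
                "valid": True,
            }
        )
        c = chronometric_curve(t)
        np.testing.assert_array_equal(c.gap, [25.0, 50.0])
        np.testing.assert_allclose(c.mean_rt, [210.0, 310.0])
        np.testing.assert_allclose(c.sd_rt, [10.0, np.std([300, 310, 320])])
        np.testing.assert_array_equal(c.n, [2, 3])

    def test_rt_curves_similar_across_trial_types(self, default_tables):
        """Mean RT vs gap is nearly identical for the three trial types."""
        curves = {t: chronometric_curve(tab) for t, tab in default_tables.items()}
        types = list(curves)
        for i in range(len(types)):
            for j in range(i + 1, len(types)):
                a, b = curves[types[i]], curves[types[j]]
                np.testing.assert_array_equal(a.gap, b.gap)
                diff = np.abs(a.mean_rt - b.mean_rt)
                assert diff.max() < 15.0
                assert diff.mean() < 7.5
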
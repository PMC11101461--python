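"""Survival, stage-association and ROC statistics for biomarker validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from snfmark.validate import (chi_square_association, dichotomize, km_estimate,
                              logrank, roc_auc, survival_validation)


class TestDichotomize:
    def test_symmetric_three_values(self):
        """{-1, 0, 1}: mean 0, SD 1, cutoffs ±0.25 → low/excluded/high."""
        g = dichotomize(pd.Series([-1.0, 0.0, 1.0]))
        assert list(g.group) == ["low", "excluded", "high"]
        assert g.lower == -0.25 and g.upper == 0.25

    def test_extreme_outlier_lands_high(self):
        values = pd.Series([0.0] * 9 + [10.0])
        g = dichotomize(values)
        assert g.group.iloc[-1] == "high"

    def test_assign_mode_has_no_exclusions(self):
        g = dichotomize(pd.Series([-1.0, -0.1, 0.1, 1.0]), mid="assign")
        assert set(g.group) <= {"low", "high"}
        assert list(g.group) == ["low", "low", "high", "high"]

    def test_cutoffs_reported(self, rng):
        v = pd.Series(rng.normal(10, 2, size=50))
        g = dichotomize(v)
        assert g.lower == pytest.approx(v.mean() - 0.25 * v.std(ddof=1))
        assert g.upper == pytest.approx(v.mean() + 0.25 * v.std(ddof=1))

    def test_affine_invariance_of_grouping(self, rng):
        v = pd.Series(rng.normal(size=40))
        a = dichotomize(v).group
        b = dichotomize(3.0 * v + 7.0).group
        assert (a == b).all()

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            dichotomize(pd.Series([2.0, 2.0, 2.0]))


class TestKaplanMeier:
    def test_all_censored_flat_one(self):
        km = km_estimate([5, 10, 15], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_three_events_product_limit(self):
        km = km_estimate([1, 2, 3], [1, 1, 1]).set_index("time")
        assert km.loc[1.0, "survival"] == pytest.approx(2 / 3)
        assert km.loc[2.0, "survival"] == pytest.approx(1 / 3)
        assert km.loc[3.0, "survival"] == pytest.approx(0.0)

    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(100, size=40).round(1) + 1
        km = km_estimate(times, np.ones_like(times)).set_index("time")
        for t in np.unique(times):
            assert km.loc[t, "survival"] == pytest.approx((times > t).mean())

    def test_monotone_in_unit_interval(self, rng):
        times = rng.exponential(50, size=30) + 1
        events = rng.integers(0, 2, size=30)
        km = km_estimate(times, events)
        s = km["survival"].to_numpy()
        assert ((s >= 0) & (s <= 1)).all()
        assert (np.diff(s) <= 1e-12).all()


def hand_logrank(times_a, events_a, times_b, events_b):
    """Independent oracle: observed-minus-expected over the risk-set table
    with hypergeometric variance, ties grouped by event time."""
    times_a, times_b = np.asarray(times_a, float), np.asarray(times_b, float)
    events_a, events_b = np.asarray(events_a, int), np.asarray(events_b, int)
    event_times = np.unique(np.r_[times_a[events_a == 1], times_b[events_b == 1]])
    O_minus_E = 0.0
    V = 0.0
    for t in event_times:
        n_a = (times_a >= t).sum()
        n_b = (times_b >= t).sum()
        d_a = ((times_a == t) & (events_a == 1)).sum()
        d_b = ((times_b == t) & (events_b == 1)).sum()
        n, d = n_a + n_b, d_a + d_b
        O_minus_E += d_a - d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    stat = O_minus_E**2 / V
    return stat, stats.chi2.sf(stat, df=1)


class TestLogrank:
    def test_identical_groups(self):
        t, e = [2, 4, 6, 8], [1, 1, 0, 1]
        stat, p = logrank(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_six_patient_hand_example(self):
        """3 vs 3 with fixed times and censoring, against the hand risk-table."""
        ta, ea = [2.0, 5.0, 9.0], [1, 1, 0]
        tb, eb = [3.0, 7.0, 11.0], [1, 0, 1]
        stat, p = logrank(ta, ea, tb, eb)
        stat_o, p_o = hand_logrank(ta, ea, tb, eb)
        assert stat == pytest.approx(stat_o, rel=1e-10)
        assert p == pytest.approx(p_o, rel=1e-10)

    def test_random_instances_match_oracle(self, rng):
        for _ in range(20):
            ta = rng.exponential(50, 12).round(0) + 1
            tb = rng.exponential(120, 12).round(0) + 1
            ea = rng.integers(0, 2, 12)
            eb = rng.integers(0, 2, 12)
            if ea.sum() + eb.sum() == 0:
                continue
            stat, p = logrank(ta, ea, tb, eb)
            stat_o, p_o = hand_logrank(ta, ea, tb, eb)
            assert stat == pytest.approx(stat_o, rel=1e-8)
            assert p == pytest.approx(p_o, rel=1e-8)

    def test_strong_separation_significant(self):
        ta = np.arange(1.0, 21.0)
        tb = ta + 100.0
        ones = np.ones(20, int)
        _, p = logrank(ta, ones, tb, ones)
        assert p < 0.001

    def test_time_rescaling_invariance(self, rng):
        ta = rng.exponential(10, 15) + 1
        tb = rng.exponential(30, 15) + 1
        ea = rng.integers(0, 2, 15)
        eb = rng.integers(0, 2, 15)
        s1, _ = logrank(ta, ea, tb, eb)
        s2, _ = logrank(ta * 365.0, ea, tb * 365.0, eb)
        assert s1 == pytest.approx(s2, rel=1e-10)

    def test_no_events_warns(self):
        with pytest.warns(UserWarning, match="no events"):
            stat, p = logrank([1, 2], [0, 0], [3, 4], [0, 0])
        assert (stat, p) == (0.0, 1.0)


def _groups(labels):
    from snfmark.validate import ExpressionGroups
    return ExpressionGroups(group=pd.Series(labels), lower=0, upper=0)


class TestChiSquare:
    def test_independent_table(self):
        g = _groups(["low"] * 20 + ["high"] * 20)
        stages = pd.Series((["1"] * 10 + ["4"] * 10) * 2)
        stat, p, dof = chi_square_association(g, stages)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_perfect_association_closed_form(self):
        """[[20,0],[0,20]]: chi-square = Σ(O−E)²/E = 40, df 1."""
        g = _groups(["low"] * 20 + ["high"] * 20)
        stages = pd.Series(["1"] * 20 + ["4"] * 20)
        stat, p, dof = chi_square_association(g, stages)
        assert stat == pytest.approx(40.0)
        assert dof == 1

    def test_row_swap_invariance(self):
        labels = ["low"] * 15 + ["high"] * 25
        stages = pd.Series(["1", "2", "4"] * 13 + ["1"])
        s1, _, _ = chi_square_association(_groups(labels), stages)
        swapped = ["high" if l == "low" else "low" for l in labels]
        s2, _, _ = chi_square_association(_groups(swapped), stages)
        assert s1 == pytest.approx(s2)

    def test_excluded_patients_dropped(self):
        g = _groups(["low"] * 10 + ["excluded"] * 5 + ["high"] * 10)
        stages = pd.Series(["1"] * 13 + ["4"] * 12)
        stat, p, dof = chi_square_association(g, stages)
        table = pd.crosstab(g.group[g.group != "excluded"],
                            stages[g.group != "excluded"])
        expected = stats.chi2_contingency(table, correction=False)[0]
        assert stat == pytest.approx(expected)


class TestRocAuc:
    def test_perfect_separation(self):
        auc, curve = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert auc == 1.0
        assert curve.iloc[0]["fpr"] == 0.0 and curve.iloc[-1]["tpr"] == 1.0

    def test_anti_discrimination_not_flipped(self):
        auc, _ = roc_auc([10, 11, 12, 1, 2, 3], [0, 0, 0, 1, 1, 1])
        assert auc == 0.0

    def test_random_scores_near_half(self, rng):
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, size=4000)
        auc, _ = roc_auc(scores, labels)
        assert abs(auc - 0.5) < 0.05

    def test_equals_mann_whitney_u(self):
        """AUC ≡ U / (n₁ n₂) on 50 seeded instances, ties included."""
        for seed in range(50):
            r = np.random.default_rng(seed)
            n1, n0 = int(r.integers(5, 40)), int(r.integers(5, 40))
            scores = np.r_[r.normal(0.5, 1, n1), r.normal(0, 1, n0)].round(1)
            labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
            auc, _ = roc_auc(scores, labels)
            u = stats.mannwhitneyu(scores[:n1], scores[n1:],
                                   alternative="two-sided").statistic
            assert auc == pytest.approx(u / (n1 * n0), rel=1e-12)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_complement_property_without_ties(self, seed):
        r = np.random.default_rng(seed)
        scores = r.permutation(30).astype(float)  # distinct scores
        labels = np.r_[np.ones(12, int), np.zeros(18, int)]
        a1, _ = roc_auc(scores, labels)
        a2, _ = roc_auc(-scores, labels)
        assert a1 + a2 == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [1, 1, 1])


def test_survival_validation_panel(small_cohort):
    expr = small_cohort.layers["mirna"].values.iloc[0]
    out = survival_validation(expr, small_cohort.clinical)
    assert out["n_low"] + out["n_high"] + out["n_excluded"] == len(expr)
    if "logrank_p" in out:
        assert 0 <= out["logrank_p"] <= 1
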
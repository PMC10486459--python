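"""ROC/AUC against pair-counting, DeLong comparison, cutoff search and
Kaplan-Meier/log-rank, each checked against an independent oracle."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cysurv.datatypes import ContractError, EvaluationError
from cysurv.evaluation import (
    bonferroni_adjust,
    compare_aucs,
    cutoff_least_misclassification,
    km_logrank,
    roc_auc,
)

DATA = Path(__file__).parent / "data"


def pair_counting_auc(scores, labels):
    """Oracle: fraction of (positive, negative) pairs ranked correctly,
    ties credited one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (pos.size * neg.size)


class TestROCAUC:
    def test_worked_example(self):
        r = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert r.auc == pytest.approx(0.75)
        assert r.auc == pytest.approx(pair_counting_auc([0.1, 0.4, 0.35, 0.8],
                                                        [0, 0, 1, 1]))

    def test_perfect_separation(self):
        r = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.auc == 1.0 and r.se == 0.0

    def test_total_ties_give_half(self):
        assert roc_auc([0.5] * 8, [0, 1] * 4).auc == 0.5

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_pair_counting_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 51))
        scores = np.round(rng.random(n), 2)  # coarse grid provokes ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            return
        r = roc_auc(scores, labels)
        assert r.auc == pytest.approx(pair_counting_auc(scores, labels), abs=1e-10)
        # trapezoidal integral of the reported ROC points agrees
        assert np.trapezoid(r.tpr, r.fpr) == pytest.approx(r.auc, abs=1e-10)

    def test_hanley_mcneil_se_matches_formula(self):
        scores = [0.1, 0.2, 0.6, 0.4, 0.8, 0.9]
        labels = [0, 0, 0, 1, 1, 1]
        r = roc_auc(scores, labels)
        a, n1, n2 = r.auc, 3, 3
        q1, q2 = a / (2 - a), 2 * a * a / (1 + a)
        var = (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n2 - 1) * (q2 - a * a)) / (n1 * n2)
        assert r.se == pytest.approx(np.sqrt(var))

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auc([0.1, 0.2], [1, 1])


class TestCompareAUCs:
    def test_self_comparison_is_null(self):
        c = compare_aucs([0.1, 0.4, 0.35, 0.8], [0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert c.delta_auc == 0.0 and c.p_value == 1.0

    def test_antisymmetry(self, rng):
        a = rng.random(40)
        b = rng.random(40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        ab = compare_aucs(a, b, y)
        ba = compare_aucs(b, a, y)
        assert ab.delta_auc == pytest.approx(-ba.delta_auc)
        assert ab.p_value == pytest.approx(ba.p_value)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ContractError):
            compare_aucs([0.1, 0.2], [0.1, 0.2, 0.3], [0, 1, 1])

    def test_detects_a_real_difference(self, rng):
        y = np.tile([0, 1], 60)
        good = y + rng.normal(0, 0.3, 120)
        noise = rng.normal(size=120)
        c = compare_aucs(good, noise, y)
        assert c.p_value < 0.01

    def test_null_calibration_small(self, rng):
        """Quick type-I check (the full 1000-replicate calibration runs in
        the acceptance suite)."""
        hits = 0
        reps = 200
        for _ in range(reps):
            y = np.tile([0, 1], 30)
            latent = y + rng.normal(0, 1.0, 60)
            a = latent + rng.normal(0, 0.5, 60)
            b = latent + rng.normal(0, 0.5, 60)
            if compare_aucs(a, b, y).p_value < 0.05:
                hits += 1
        assert hits <= 25  # generous 3-sigma bound around 10


class TestBonferroni:
    def test_three_comparisons_at_5_percent(self):
        assert bonferroni_adjust(0.05, 3) == 0.017

    def test_identity_and_arithmetic(self):
        assert bonferroni_adjust(0.05, 1) == 0.05
        assert bonferroni_adjust(0.10, 5) == 0.02

    def test_zero_comparisons_rejected(self):
        with pytest.raises(ContractError):
            bonferroni_adjust(0.05, 0)


class TestCutoff:
    def test_separable_case_returns_midpoint(self):
        assert cutoff_least_misclassification(
            [0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]
        ) == pytest.approx(0.5)

    def test_matches_exhaustive_search(self, rng):
        def exhaustive(scores, labels):
            distinct = np.unique(scores)
            cands = (distinct[:-1] + distinct[1:]) / 2
            best = None
            for t in cands:
                pred = scores >= t
                err = int((pred & (labels == 0)).sum()
                          + (~pred & (labels == 1)).sum())
                if best is None or err < best[1]:
                    best = (t, err)
            return best

        scores = rng.random(200)
        labels = (scores + rng.normal(0, 0.4, 200) > 0.5).astype(int)
        thr = cutoff_least_misclassification(scores, labels)
        t_star, err_star = exhaustive(scores, labels)
        pred = scores >= thr
        err = int((pred & (labels == 0)).sum() + (~pred & (labels == 1)).sum())
        assert err == err_star
        assert thr == pytest.approx(t_star)

    def test_inverted_labels_still_minimize_on_given_labels(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        thr = cutoff_least_misclassification(scores, [1, 1, 0, 0])
        pred = scores >= thr
        labels = np.array([1, 1, 0, 0])
        err = int((pred & (labels == 0)).sum() + (~pred & (labels == 1)).sum())
        # exhaustive over midpoints 0.15/0.5/0.85 gives errors 3/4/3;
        # the tie breaks to the lower threshold
        assert err == 3
        assert thr == pytest.approx(0.15)


class TestKaplanMeier:
    def test_hand_computed_12_subject_fixture(self):
        """Log-rank on a 12-subject table verified by the textbook
        observed-vs-expected computation: O_A=4, E_A=4.351804, V=2.201968,
        chi-square = (O-E)^2/V = 0.056207, p = 0.8126."""
        df = pd.read_csv(DATA / "km_logrank_fixture.csv")
        res = km_logrank(df.survival_months, df.event, df.group)
        assert res.statistic == pytest.approx(0.056207, abs=1e-5)
        assert res.p_value == pytest.approx(0.812595, abs=1e-5)

    def test_identical_groups_are_indistinguishable(self):
        t = [5, 10, 15, 5, 10, 15]
        e = [1, 1, 0, 1, 1, 0]
        g = ["a"] * 3 + ["b"] * 3
        res = km_logrank(t, e, g)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_no_events_flagged_degenerate(self):
        res = km_logrank([10, 20, 30, 40], [0, 0, 0, 0], ["a", "a", "b", "b"])
        assert res.degenerate
        assert np.isnan(res.statistic)
        for curve in res.curves.values():
            assert np.allclose(curve.survival, 1.0)

    def test_km_without_censoring_equals_empirical_survival(self, rng):
        times = rng.integers(1, 40, 20).astype(float)
        res = km_logrank(
            np.concatenate([times, [50.0]]),
            np.ones(21, bool),
            ["a"] * 20 + ["b"],
        )
        curve = res.curves["a"]
        for t, s in zip(curve.time, curve.survival):
            assert s == pytest.approx((times > t).mean())

    def test_survival_curves_start_at_one_and_decrease(self, small_cohort):
        _, _, records, _ = small_cohort
        t = [r.survival_months for r in records]
        e = [r.event for r in records]
        g = ["alive" if r.label_5yr else "dead" for r in records]
        res = km_logrank(t, e, g)
        for curve in res.curves.values():
            surv = curve.survival.to_numpy()
            assert surv[0] <= 1.0 + 1e-12
            assert np.all(np.diff(surv) <= 1e-12)
        assert sum(res.group_sizes.values()) == len(records)

    def test_empty_group_rejected(self):
        with pytest.raises(EvaluationError):
            km_logrank([1, 2], [1, 1], ["a", "a"])
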
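"""Metrics, stratified splitting, Wilcoxon signed-rank and BH correction.

Independent oracles: scikit-learn for the binary metrics,
scipy.stats.wilcoxon for exact signed-rank p-values, statsmodels for
the Benjamini-Hochberg adjustment.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn import metrics as skm
from statsmodels.stats.multitest import multipletests

from lcmsnet import (
    ConfusionCounts,
    bh_adjust,
    binary_metrics,
    confusion_counts,
    macro_metrics,
    stratified_split,
    wilcoxon_signed_rank,
)


class TestConfusionCounts:
    def test_hand_enumerated_example(self):
        c = confusion_counts(["A", "A", "B", "B"], ["A", "B", "B", "B"], "A")
        assert (c.tp, c.fn, c.tn, c.fp) == (1, 1, 2, 0)

    def test_perfect_prediction(self):
        c = confusion_counts(["A", "B"], ["A", "B"], "A")
        assert c.fp == 0 and c.fn == 0

    def test_positive_class_absent(self):
        c = confusion_counts(["B", "B"], ["B", "B"], "A")
        assert c.tp == 0 and c.fn == 0 and c.tn == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(["A"], ["A", "B"], "A")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)


class TestBinaryMetrics:
    def test_hand_substitution(self):
        r = binary_metrics(ConfusionCounts(tp=8, tn=5, fp=2, fn=1))
        assert r.accuracy == pytest.approx(13 / 16)
        assert r.sensitivity == pytest.approx(8 / 9)
        assert r.specificity == pytest.approx(5 / 7)
        assert r.f1 == pytest.approx(16 / 19)

    def test_perfect_classifier(self):
        r = binary_metrics(ConfusionCounts(tp=10, tn=10, fp=0, fn=0))
        assert (r.accuracy, r.sensitivity, r.specificity, r.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_degenerate_never_positive(self):
        r = binary_metrics(ConfusionCounts(tp=0, fp=0, fn=5, tn=5))
        assert r.sensitivity == 0.0 and r.f1 == 0.0 and r.specificity == 1.0

    def test_zero_denominators_flagged_undefined(self):
        r = binary_metrics(ConfusionCounts(tp=0, tn=3, fp=0, fn=0))
        assert np.isnan(r.sensitivity) and np.isnan(r.f1)
        assert set(r.undefined) == {"sensitivity", "f1"}

    def test_matches_sklearn_on_random_labels(self, rng):
        y_true = rng.integers(0, 2, 200)
        y_pred = rng.integers(0, 2, 200)
        r = binary_metrics(confusion_counts(y_true, y_pred, 1))
        assert r.accuracy == pytest.approx(skm.accuracy_score(y_true, y_pred))
        assert r.sensitivity == pytest.approx(skm.recall_score(y_true, y_pred))
        assert r.f1 == pytest.approx(skm.f1_score(y_true, y_pred))


class TestMacroMetrics:
    def test_macro_f1_matches_sklearn(self, rng):
        y_true = rng.choice(list("ABC"), 300)
        y_pred = rng.choice(list("ABC"), 300)
        report = macro_metrics(y_true, y_pred)
        assert report.macro.f1 == pytest.approx(skm.f1_score(y_true, y_pred, average="macro"))
        assert report.overall_accuracy == pytest.approx(skm.accuracy_score(y_true, y_pred))

    def test_invariant_under_class_relabeling(self, rng):
        y_true = rng.choice(list("ABC"), 200)
        y_pred = rng.choice(list("ABC"), 200)
        relabel = {"A": "Z", "B": "Y", "C": "X"}
        a = macro_metrics(y_true, y_pred)
        b = macro_metrics([relabel[y] for y in y_true], [relabel[y] for y in y_pred])
        assert a.macro.f1 == pytest.approx(b.macro.f1)
        assert a.macro.specificity == pytest.approx(b.macro.specificity)

    def test_one_vs_rest_accuracy_exceeds_overall_on_imbalanced_data(self, rng):
        # the large "rest" group inflates binary accuracy above the
        # multiclass fraction of exact matches
        y_true = ["A"] * 80 + ["B"] * 10 + ["C"] * 10
        y_pred = list(rng.permutation(y_true))
        report = macro_metrics(y_true, y_pred)
        class_accs = [r.accuracy for r in report.per_class.values()]
        assert min(class_accs[1:]) > report.overall_accuracy

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            macro_metrics([], [])


class TestStratifiedSplit:
    def test_75_25_proportions_preserved(self):
        labels = ["A"] * 80 + ["B"] * 20
        assignment = stratified_split(labels, test_fraction=0.25, seed=0)
        test_labels = [l for l, a in zip(labels, assignment) if a == 1]
        assert test_labels.count("A") == 20
        assert test_labels.count("B") == 5

    def test_10_fold_balanced(self):
        labels = np.repeat(list("ABCDE"), 20)
        assignment = stratified_split(labels, k=10, seed=0)
        for fold in range(10):
            fold_labels = labels[assignment == fold]
            assert len(fold_labels) == 10
            assert all((fold_labels == c).sum() == 2 for c in "ABCDE")

    def test_folds_partition_the_index_set(self, rng):
        labels = rng.choice(list("AB"), 57)
        assignment = stratified_split(labels, k=5, seed=1)
        assert assignment.size == 57
        assert set(assignment) == set(range(5))

    def test_deterministic_given_seed(self):
        labels = ["A"] * 40 + ["B"] * 20
        a = stratified_split(labels, test_fraction=0.25, seed=3)
        b = stratified_split(labels, test_fraction=0.25, seed=3)
        assert np.array_equal(a, b)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(["A"] * 20 + ["B"] * 3, k=5)


class TestWilcoxon:
    def test_hand_ranked_example(self):
        r = wilcoxon_signed_rank([1, -2, 3, -4, 5])
        assert r.r_plus == 9.0
        assert r.r_minus == 6.0
        assert r.t_statistic == 6.0

    def test_all_positive_gives_t_zero(self):
        r = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert r.t_statistic == 0.0

    def test_rank_sum_identity(self, rng):
        for _ in range(20):
            d = rng.normal(size=rng.integers(2, 25))
            r = wilcoxon_signed_rank(d)
            n = r.n_nonzero
            assert r.r_plus + r.r_minus == pytest.approx(n * (n + 1) / 2)

    @pytest.mark.parametrize("n", [3, 5, 8, 10])
    def test_exact_p_matches_scipy_enumeration(self, n, rng):
        for _ in range(10):
            d = rng.normal(size=n)
            d = d[d != 0]
            r = wilcoxon_signed_rank(d, alternative="greater")
            expected = stats.wilcoxon(d, alternative="greater", method="exact").pvalue
            assert r.method == "exact"
            assert r.p_value == pytest.approx(expected)

    def test_two_sided_exact_matches_scipy(self, rng):
        d = rng.normal(size=8)
        r = wilcoxon_signed_rank(d, alternative="two-sided")
        expected = stats.wilcoxon(d, alternative="two-sided", method="exact").pvalue
        assert r.p_value == pytest.approx(expected)

    def test_normal_approximation_close_to_scipy(self, rng):
        d = rng.normal(loc=0.3, size=40)
        r = wilcoxon_signed_rank(d, alternative="greater")
        assert r.method == "normal-approximation"
        expected = stats.wilcoxon(d, alternative="greater", method="approx",
                                  correction=True).pvalue
        assert r.p_value == pytest.approx(expected, rel=1e-3)

    def test_zero_differences_dropped(self):
        r = wilcoxon_signed_rank([0.0, 1.0, -2.0, 0.0])
        assert r.n_nonzero == 2

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])


class TestBHAdjust:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3])[0] == pytest.approx(0.3)

    def test_matches_statsmodels_on_random_vectors(self, rng):
        for _ in range(10):
            p = rng.uniform(0, 1, rng.integers(1, 30))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected)

    def test_adjusted_at_least_raw_and_capped(self, rng):
        p = rng.uniform(0, 1, 50)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0).all()

    def test_monotone_in_raw_order(self, rng):
        p = rng.uniform(0, 1, 30)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestWilcoxonProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=30)
           .filter(lambda d: any(x != 0 for x in d)))
    def test_rank_sum_identity_holds_for_arbitrary_differences(self, d):
        r = wilcoxon_signed_rank(d)
        n = r.n_nonzero
        assert r.r_plus + r.r_minus == pytest.approx(n * (n + 1) / 2)
        assert r.t_statistic == min(r.r_plus, r.r_minus)
        assert 0.0 <= r.p_value <= 1.0


class TestBHProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_adjustment_dominates_raw_and_preserves_order(self, p):
        q = bh_adjust(p)
        p = np.asarray(p)
        assert (q >= p - 1e-12).all()
        assert (q <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()
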
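"""Evaluation protocol: confusion-based metrics, stratified splits, and
classifier comparison by the Wilcoxon signed-rank test with
Benjamini-Hochberg correction.

Metrics follow the usual confusion-matrix definitions:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 TP / (2 TP + FP + FN)

Multiclass problems are reported one-vs-rest per class and
macro-averaged (unweighted mean over classes); per-class values with a
zero denominator are flagged undefined and excluded from the macro mean
with an explicit count.  The overall multiclass accuracy (fraction of
exact label matches) is reported separately — with one-vs-rest binary
accuracies the large "negative" group inflates per-class accuracy well
above the multiclass value on imbalanced data.

Model comparison ranks per-fold performance differences d_i of two
classifiers over stratified cross-validation folds:
R+ = sum of ranks of positive d, R- of negative d, T = min(R+, R-),
with an exact p-value by full sign enumeration for small N and a normal
approximation (tie and continuity corrected) otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "MacroReport",
    "WilcoxonResult",
    "confusion_counts",
    "binary_metrics",
    "macro_metrics",
    "stratified_split",
    "wilcoxon_signed_rank",
    "bh_adjust",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts for one positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy / sensitivity / specificity / F1, NaN where undefined.

    ``undefined`` names the metrics whose denominator was zero.
    ``scope`` records what the report covers: 'overall', a per-class
    one-vs-rest report, or a macro average.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    f1: float
    scope: str = "overall"
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
        }


@dataclass(frozen=True)
class MacroReport:
    """One-vs-rest per-class reports plus their macro average.

    ``overall_accuracy`` is the plain multiclass fraction of exact
    matches; ``n_undefined_excluded`` counts per-class metric values
    left out of the macro means because their denominator was zero.
    """

    per_class: dict[str, MetricsReport]
    macro: MetricsReport
    overall_accuracy: float
    n_undefined_excluded: int = 0


def confusion_counts(
    y_true: Sequence, y_pred: Sequence, positive_class
) -> ConfusionCounts:
    """Binary confusion counts treating ``positive_class`` against the rest.

    Rejected predictions must be filtered out by the caller before
    counting.
    """
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    t = np.asarray(y_true) == positive_class
    p = np.asarray(y_pred) == positive_class
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def binary_metrics(counts: ConfusionCounts, scope: str = "overall") -> MetricsReport:
    """Accuracy, sensitivity, specificity and F1 from binary counts.

    A zero denominator yields NaN for that metric and its name in
    ``undefined``.
    """
    undefined = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return float("nan")
        return num / den

    accuracy = ratio(counts.tp + counts.tn, counts.total, "accuracy")
    sensitivity = ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    specificity = ratio(counts.tn, counts.tn + counts.fp, "specificity")
    f1 = ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn, "f1")
    return MetricsReport(accuracy, sensitivity, specificity, f1, scope, tuple(undefined))


def macro_metrics(y_true: Sequence, y_pred: Sequence, classes: Sequence | None = None) -> MacroReport:
    """One-vs-rest metrics per class plus the unweighted macro average."""
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    if classes is None:
        classes = sorted(set(y_true))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    per_class = {
        str(c): binary_metrics(confusion_counts(y_true, y_pred, c), scope=f"class:{c}")
        for c in classes
    }
    metric_names = ("accuracy", "sensitivity", "specificity", "f1")
    macro_values = {}
    n_excluded = 0
    for name in metric_names:
        values = np.array([getattr(r, name) for r in per_class.values()])
        valid = ~np.isnan(values)
        n_excluded += int((~valid).sum())
        macro_values[name] = float(values[valid].mean()) if valid.any() else float("nan")
    macro = MetricsReport(scope="macro", undefined=(), **macro_values)
    overall = float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))
    return MacroReport(per_class=per_class, macro=macro,
                       overall_accuracy=overall, n_undefined_excluded=n_excluded)


def stratified_split(
    labels: Sequence,
    test_fraction: float | None = None,
    k: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Stratified assignment of samples to subsets or folds.

    With ``test_fraction`` (e.g. 0.25 for the 75/25 convention), returns
    an array of 0 (train) / 1 (test) preserving per-class proportions
    within one sample.  With ``k``, returns fold indices 0..k-1 from
    stratified k-fold (folds disjoint and exhaustive).  Deterministic
    given ``seed``.
    """
    labels = np.asarray(labels)
    if (test_fraction is None) == (k is None):
        raise ValueError("specify exactly one of test_fraction or k")
    if test_fraction is not None:
        if not 0 < test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        idx = np.arange(labels.size)
        _, test_idx = train_test_split(
            idx, test_size=test_fraction, stratify=labels, random_state=seed
        )
        assignment = np.zeros(labels.size, dtype=int)
        assignment[test_idx] = 1
        return assignment
    _, class_counts = np.unique(labels, return_counts=True)
    if class_counts.min() < k:
        raise ValueError(f"every class needs at least k={k} members for k-fold")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(labels.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
        assignment[test_idx] = fold
    return assignment


@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank test outcome: rank sums, T statistic and p-value."""

    differences: tuple[float, ...]
    r_plus: float
    r_minus: float
    t_statistic: float
    p_value: float
    method: Literal["exact", "normal-approximation"]
    alternative: str = "greater"
    n_nonzero: int = 0


def _exact_p(ranks: np.ndarray, observed: float, tail: str) -> float:
    """P(R_minus <= observed) (tail='le') or >= (tail='ge') by full enumeration.

    Enumerates all 2^N sign assignments of the ranked |d| values, which
    remains valid under mid-ranks from ties.
    """
    n = ranks.size
    count = 0
    for signs in itertools.product((0, 1), repeat=n):
        r_minus = float(np.dot(signs, ranks))
        if tail == "le" and r_minus <= observed + 1e-12:
            count += 1
        elif tail == "ge" and r_minus >= observed - 1e-12:
            count += 1
    return count / 2**n


def wilcoxon_signed_rank(
    differences: Sequence[float],
    alternative: Literal["greater", "less", "two-sided"] = "greater",
    exact_threshold: int = 15,
) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired performance differences.

    Zero differences are dropped; |d| are ranked ascending with
    mid-ranks for ties.  ``alternative='greater'`` tests whether the
    differences are systematically positive (the first classifier
    outperforms the second).  Exact p by full 2^N' sign enumeration when
    the number of nonzero differences N' <= ``exact_threshold``, else a
    normal approximation with tie and continuity corrections.
    """
    d = np.asarray(differences, dtype=np.float64)
    if d.size == 0:
        raise ValueError("need at least one difference")
    nonzero = d[d != 0]
    n = nonzero.size
    if n == 0:
        raise ValueError("all differences are zero: test undefined")
    ranks = rankdata(np.abs(nonzero))
    r_plus = float(ranks[nonzero > 0].sum())
    r_minus = float(ranks[nonzero < 0].sum())
    t_stat = min(r_plus, r_minus)

    if n <= exact_threshold:
        method = "exact"
        if alternative == "greater":
            p = _exact_p(ranks, r_minus, "le")
        elif alternative == "less":
            p = _exact_p(ranks, r_minus, "ge")
        else:
            p = min(1.0, 2 * min(_exact_p(ranks, r_minus, "le"), _exact_p(ranks, r_minus, "ge")))
    else:
        method = "normal-approximation"
        mean = n * (n + 1) / 4.0
        # variance with tie correction over groups of tied |d|
        _, tie_counts = np.unique(np.abs(nonzero), return_counts=True)
        var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
        sd = math.sqrt(var)

        def tail_p(stat: float, tail: str) -> float:
            # continuity correction of 0.5 toward the mean
            if tail == "le":
                z = (stat - mean + 0.5) / sd
                return 0.5 * math.erfc(-z / math.sqrt(2))
            z = (stat - mean - 0.5) / sd
            return 0.5 * math.erfc(z / math.sqrt(2))

        if alternative == "greater":
            p = tail_p(r_minus, "le")
        elif alternative == "less":
            p = tail_p(r_minus, "ge")
        else:
            p = min(1.0, 2 * min(tail_p(t_stat, "le"), tail_p(t_stat, "ge")))
    return WilcoxonResult(
        differences=tuple(float(x) for x in d),
        r_plus=r_plus,
        r_minus=r_minus,
        t_statistic=float(t_stat),
        p_value=float(min(1.0, p)),
        method=method,
        alternative=alternative,
        n_nonzero=n,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(m)
    out[order] = adjusted_sorted
    return out
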
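"""Label assignment with an optional reject option.

By default the class with the highest averaged probability wins.  For
high-stakes screening a prediction can instead be withheld when the
confidence margin — the difference between the top two class
probabilities — falls below a threshold.  The threshold is selected on
a validation split (by convention 10% of the training data) as the
candidate maximizing macro specificity over the accepted samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .evaluation import binary_metrics, confusion_counts

__all__ = [
    "REJECTED",
    "PredictionResult",
    "confidence_margin",
    "classify_with_reject",
    "select_threshold",
    "DEFAULT_THRESHOLD_GRID",
]

REJECTED = "REJECTED"

# candidate margin thresholds searched during specificity optimisation
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = tuple(np.round(np.arange(0.0, 1.0, 0.05), 2))


@dataclass(frozen=True)
class PredictionResult:
    """Final decision for one sample.

    ``predicted`` is a class label or the ``REJECTED`` sentinel;
    ``margin`` is top-1 minus top-2 probability.
    """

    probs: np.ndarray
    predicted: str
    margin: float
    sample_id: str = ""

    @property
    def rejected(self) -> bool:
        return self.predicted == REJECTED


def confidence_margin(probs: Sequence[float]) -> float:
    """Difference between the largest and second-largest probability."""
    p = np.asarray(probs, dtype=np.float64)
    if p.size < 2:
        raise ValueError("confidence margin needs at least 2 classes")
    top2 = np.partition(p, -2)[-2:]
    return float(top2[1] - top2[0])


def classify_with_reject(
    probs: Sequence[float],
    class_order: Sequence[str],
    threshold: float = 0.0,
    sample_id: str = "",
) -> PredictionResult:
    """Argmax classification with margin-based rejection.

    The sample is rejected iff its margin is strictly below
    ``threshold`` (so threshold 0 never rejects).  Probability ties in
    the argmax break toward the lowest index in ``class_order``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    p = np.asarray(probs, dtype=np.float64)
    if p.size != len(class_order):
        raise ValueError("probs length must match class_order")
    margin = confidence_margin(p)
    if margin < threshold:
        predicted = REJECTED
    else:
        predicted = str(class_order[int(np.argmax(p))])  # argmax takes the first maximum
    return PredictionResult(probs=p, predicted=predicted, margin=margin, sample_id=sample_id)


def select_threshold(
    probs: np.ndarray,
    y_true: Sequence[str],
    class_order: Sequence[str],
    candidates: Sequence[float] = DEFAULT_THRESHOLD_GRID,
) -> float:
    """Pick the margin threshold maximizing macro specificity on a validation set.

    For each candidate, samples whose margin falls below it are rejected
    and excluded from the confusion counts; macro specificity (one-vs-
    rest, unweighted over classes, undefined classes skipped) is
    computed over the accepted samples.  Candidates rejecting the whole
    validation set are disqualified.  Ties break toward the smallest
    threshold (fewest rejections).
    """
    probs = np.asarray(probs, dtype=np.float64)
    y_true = np.asarray(y_true)
    if probs.shape[0] != y_true.size or y_true.size == 0:
        raise ValueError("need a non-empty validation set with matching labels")
    for c in candidates:
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"candidate threshold {c} outside [0, 1]")
    margins = np.array([confidence_margin(p) for p in probs])
    argmax_labels = np.array([str(class_order[int(np.argmax(p))]) for p in probs])

    best_threshold = None
    best_score = -np.inf
    for threshold in sorted(candidates):
        accepted = margins >= threshold
        if not accepted.any():
            continue
        specs = []
        for c in class_order:
            counts = confusion_counts(y_true[accepted], argmax_labels[accepted], c)
            spec = binary_metrics(counts).specificity
            if not np.isnan(spec):
                specs.append(spec)
        if not specs:
            continue
        score = float(np.mean(specs))
        if score > best_score + 1e-12:  # strict improvement; ties keep the smaller threshold
            best_score = score
            best_threshold = threshold
    if best_threshold is None:
        raise ValueError("every candidate threshold rejects the entire validation set")
    return float(best_threshold)
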
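"""Training-set expansion: random RT-shift augmentation and oversampling.

RT-shift augmentation simulates the chromatographic drift seen between
runs acquired months apart: each augmented copy of a sample has all of
its points shifted by a single delta drawn uniformly from
``[-max_shift, +max_shift]`` (default 10 s).  Shifts are applied to the
raw point cloud before binning; points pushed outside the acquisition
span are dropped.  Random oversampling duplicates minority-class items
until every class matches the majority count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, TypeVar

import numpy as np

from .io import Sample

__all__ = ["AugmentConfig", "shift_rt", "augment_dataset", "oversample"]

T = TypeVar("T")


@dataclass(frozen=True)
class AugmentConfig:
    """RT-shift augmentation settings.

    ``max_shift``: largest |shift| in seconds (default 10 s).
    ``copies_per_sample``: shifted copies emitted per input sample,
    in addition to the original.
    """

    max_shift: float = 10.0
    copies_per_sample: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_shift < 0:
            raise ValueError("max_shift must be >= 0")
        if self.copies_per_sample < 0:
            raise ValueError("copies_per_sample must be >= 0")


def shift_rt(sample: Sample, delta: float) -> Sample:
    """Shift every point's retention time by ``delta`` seconds.

    Points leaving the acquisition span are dropped; label, batch and
    span are preserved and the (rt, mz) sort order is restored.
    """
    rt = sample.rt + delta
    lo, hi = sample.acquisition_span
    keep = (rt >= lo) & (rt <= hi)
    return sample.replace_points(rt[keep], sample.mz[keep], sample.intensity[keep])


def augment_dataset(samples: Sequence[Sample], config: AugmentConfig) -> list[Sample]:
    """Original samples plus ``copies_per_sample`` RT-shifted copies each.

    Deltas are drawn uniformly from ``[-max_shift, +max_shift]``,
    deterministically from ``config.seed``.  Labels and batch ids are
    inherited unchanged.
    """
    rng = np.random.default_rng(config.seed)
    out: list[Sample] = []
    for sample in samples:
        out.append(sample)
        for copy_index in range(config.copies_per_sample):
            delta = float(rng.uniform(-config.max_shift, config.max_shift))
            shifted = shift_rt(sample, delta)
            shifted.sample_id = f"{sample.sample_id}_aug{copy_index}"
            out.append(shifted)
    return out


def oversample(items: Sequence[T], labels: Sequence[str], seed: int = 0) -> tuple[list[T], list[str]]:
    """Random oversampling to the majority-class count.

    Every class is brought up to the size of the largest class by
    drawing duplicates uniformly with replacement from that class's
    items.  All original items are retained (originals first, then the
    duplicates); deterministic given ``seed``.
    """
    if len(items) != len(labels):
        raise ValueError("items and labels must have equal length")
    if not items:
        raise ValueError("cannot oversample an empty collection")
    labels = list(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if (counts == 0).any():
        raise ValueError("every class must have at least one item")
    target = int(counts.max())
    rng = np.random.default_rng(seed)
    out_items = list(items)
    out_labels = list(labels)
    label_array = np.asarray(labels)
    for cls, count in zip(classes, counts):
        deficit = target - int(count)
        if deficit == 0:
            continue
        member_idx = np.flatnonzero(label_array == cls)
        picks = rng.choice(member_idx, size=deficit, replace=True)
        for i in picks:
            out_items.append(items[int(i)])
            out_labels.append(labels[int(i)])
    return out_items, out_labels
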
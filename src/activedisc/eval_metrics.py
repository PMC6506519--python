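"""Pixel-level segmentation metrics and classification accuracy.

Metrics follow the standard confusion-matrix definitions, with the algorithm
mask ``A`` compared against the manual/reference mask ``M`` over the full
raster.  Jaccard is |A∩M| / |A∪M| and Dice is 2|A∩M| / (|A|+|M|), related by
D = 2J / (1+J).  Metrics with a zero denominator are reported as ``None``
(explicitly undefined), never coerced to 0 or 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "segmentation_metrics",
    "overall_classification_accuracy",
    "ClassificationAccuracy",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(pred_mask, ref_mask) -> ConfusionCounts:
    """Per-pixel confusion counts between a predicted and a reference mask."""
    pred = np.asarray(pred_mask).astype(bool)
    ref = np.asarray(ref_mask).astype(bool)
    if pred.shape != ref.shape:
        raise InvalidArgumentError(
            f"mask shapes differ: {pred.shape} vs {ref.shape}"
        )
    tp = int(np.count_nonzero(pred & ref))
    tn = int(np.count_nonzero(~pred & ~ref))
    fp = int(np.count_nonzero(pred & ~ref))
    fn = int(np.count_nonzero(~pred & ref))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def segmentation_metrics(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity, accuracy, Jaccard and Dice from counts.

    Undefined ratios (zero denominator) come back as ``None``.
    """
    return {
        "sensitivity": _ratio(c.tp, c.tp + c.fn),
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "accuracy": _ratio(c.tp + c.tn, c.total),
        "jaccard": _ratio(c.tp, c.tp + c.fp + c.fn),
        "dice": _ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    }


class ClassificationAccuracy(NamedTuple):
    n_correct: int
    n_total: int
    fraction: float
    percent: str  # rendered to two decimals, e.g. "92.20%"


def overall_classification_accuracy(pred_labels: Sequence, ref_labels: Sequence) -> ClassificationAccuracy:
    """Fraction of images whose predicted label matches the reference label."""
    pred = list(pred_labels)
    ref = list(ref_labels)
    if not pred or len(pred) != len(ref):
        raise InvalidArgumentError(
            f"label lists must be non-empty and equal length ({len(pred)} vs {len(ref)})"
        )
    n_correct = sum(1 for p, r in zip(pred, ref) if p == r)
    frac = n_correct / len(pred)
    return ClassificationAccuracy(
        n_correct=n_correct,
        n_total=len(pred),
        fraction=frac,
        percent=f"{100.0 * frac:.2f}%",
    )
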
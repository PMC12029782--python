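"""Instance-segmentation evaluation: IoU matching, confusion counts, and
the derived metrics.

Predicted and ground-truth masks of one class are matched greedily,
one-to-one, in order of descending IoU.  A matched pair with IoU at or
above the threshold (0.5 by default) is a true positive; unmatched
predictions are false positives and unmatched truths false negatives.
Object-level true negatives are not derivable from masks alone, so the
caller supplies ``negative_units`` — the number of evaluation units
containing no object of the class — and the false positives found are
subtracted from it (floored at zero).

Metric conventions
------------------
precision = TP/(TP+FP), recall = TP/(TP+FN), accuracy = (TP+TN)/total,
each reported TRUNCATED (floored) to two decimals, and F1 is the harmonic
mean of the truncated precision and recall, itself truncated.  Truncation
rather than rounding is deliberate: it is the only convention under which
printed report values such as precision 0.52 from counts 9/17 (= 0.529)
or accuracy 0.91 from 44/48 (= 0.9167) are reproduced.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotations_io import ClassLabel

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "UndefinedMetricError",
    "iou",
    "match_and_count",
    "precision",
    "recall",
    "f1",
    "accuracy",
    "metric_set",
    "metrics_report",
    "truncate2",
]


class UndefinedMetricError(ZeroDivisionError):
    """Raised when a metric's denominator is zero."""


@dataclass(frozen=True)
class ConfusionCounts:
    """Object-level TP/FP/FN/TN tallies for one class."""

    tp: int
    fp: int
    fn: int
    tn: int
    class_label: ClassLabel | None = None

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricSet:
    """Precision/recall/F1/accuracy, truncated to two decimals."""

    precision: float
    recall: float
    f1: float
    accuracy: float


def truncate2(x: float) -> float:
    """Floor to two decimals (0.529 -> 0.52); reporting convention."""
    # tiny epsilon so that float artifacts like 0.9299999... still
    # truncate to the intended 0.93
    return math.floor(x * 100 + 1e-9) / 100


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two boolean masks of the same shape.

    Two empty masks have IoU 0 by convention (with a warning): an empty
    pair carries no overlap evidence.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        warnings.warn("IoU of two empty masks is defined as 0", stacklevel=2)
        return 0.0
    return np.count_nonzero(a & b) / union


def match_and_count(
    preds: Mapping[ClassLabel, Sequence[np.ndarray]],
    truths: Mapping[ClassLabel, Sequence[np.ndarray]],
    iou_threshold: float = 0.5,
    negative_units: int = 0,
) -> dict[ClassLabel, ConfusionCounts]:
    """Greedy one-to-one IoU matching producing per-class confusion counts.

    Pairs are consumed in descending IoU; a pair at or above the threshold
    is a TP, leftovers become FP (prediction) or FN (truth).  TN is
    ``negative_units`` minus the class's FP count, floored at zero.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError(f"iou_threshold must lie in (0, 1], got {iou_threshold}")
    if negative_units < 0:
        raise ValueError("negative_units must be non-negative")

    out: dict[ClassLabel, ConfusionCounts] = {}
    for label in ClassLabel:
        p = list(preds.get(label, ()))
        t = list(truths.get(label, ()))
        pairs = [
            (iou(p[i], t[j]), i, j)
            for i in range(len(p))
            for j in range(len(t))
        ]
        pairs.sort(key=lambda x: (-x[0], x[1], x[2]))
        matched_p: set[int] = set()
        matched_t: set[int] = set()
        tp = 0
        for score, i, j in pairs:
            if score < iou_threshold:
                break
            if i in matched_p or j in matched_t:
                continue
            matched_p.add(i)
            matched_t.add(j)
            tp += 1
        fp = len(p) - tp
        fn = len(t) - tp
        tn = max(0, negative_units - fp)
        out[label] = ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn, class_label=label)
    return out


def precision(c: ConfusionCounts) -> float:
    """TP/(TP+FP), truncated to two decimals."""
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: no positive predictions")
    return truncate2(c.tp / (c.tp + c.fp))


def recall(c: ConfusionCounts) -> float:
    """TP/(TP+FN), truncated to two decimals."""
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("recall undefined: no positive truths")
    return truncate2(c.tp / (c.tp + c.fn))


def f1(c: ConfusionCounts) -> float:
    """Harmonic mean of the TRUNCATED precision and recall, truncated.

    Computing from the already-truncated two-decimal values is part of
    the reporting convention, not an approximation shortcut.
    """
    p = precision(c)
    r = recall(c)
    if p + r == 0:
        raise UndefinedMetricError("f1 undefined: precision + recall is zero")
    return truncate2(2 * p * r / (p + r))


def accuracy(c: ConfusionCounts) -> float:
    """(TP+TN)/total, truncated to two decimals."""
    if c.total == 0:
        raise ValueError("accuracy undefined: empty confusion counts")
    return truncate2((c.tp + c.tn) / c.total)


def metric_set(c: ConfusionCounts) -> MetricSet:
    """All four metrics of one confusion-count cell."""
    return MetricSet(
        precision=precision(c), recall=recall(c), f1=f1(c), accuracy=accuracy(c)
    )


def metrics_report(
    counts_per_run: Mapping[str, Mapping[ClassLabel, ConfusionCounts]],
) -> pd.DataFrame:
    """Metric x class table with one column per run.

    Rows are (Metric, Class); columns follow the input run order.  Cells
    with an undefined metric are left as NaN.  An empty input yields a
    header-only frame.
    """
    metric_fns = {
        "F1 Score": f1,
        "Precision": precision,
        "Accuracy": accuracy,
        "Recall": recall,
    }
    index = pd.MultiIndex.from_tuples(
        [
            (metric, label.value)
            for metric in metric_fns
            for label in ClassLabel
        ],
        names=["Metric", "Class"],
    )
    frame = pd.DataFrame(index=index, columns=list(counts_per_run), dtype=float)
    for run, per_class in counts_per_run.items():
        for label, c in per_class.items():
            for metric, fn in metric_fns.items():
                try:
                    frame.loc[(metric, label.value), run] = fn(c)
                except (UndefinedMetricError, ValueError):
                    logger.warning(
                        "%s undefined for %s in run %s", metric, label.value, run
                    )
    return frame
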
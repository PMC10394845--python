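"""Loss and segmentation-quality metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "cross_entropy_loss", "segmentation_metrics",
           "ClassMetrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ClassMetrics:
    iou: float
    accuracy: float
    precision: float
    recall: float


def cross_entropy_loss(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Mean negative log-probability of the true class.

    Probabilities are clamped at 1e-12 so the loss stays finite.
    """
    probabilities = np.asarray(probabilities, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    n, k = probabilities.shape
    if labels.shape != (n,):
        raise ValueError("labels must have one entry per probability row")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    q = np.clip(probabilities[np.arange(n), labels], 1e-12, None)
    return float(-np.log(q).mean())


def _ratio(num: int, den: int, class_absent: bool) -> float:
    if den == 0:
        return 1.0 if class_absent else 0.0
    return num / den


def segmentation_metrics(
    pred: np.ndarray, truth: np.ndarray, classes=(0, 1)
) -> dict[int, ClassMetrics]:
    """Per-class IoU, accuracy, precision and recall.

    Undefined 0/0 ratios report 1 when the class is absent from both the
    prediction and the truth, else 0.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have equal length")
    out = {}
    for c in classes:
        p = pred == c
        t = truth == c
        tp = int(np.sum(p & t))
        fp = int(np.sum(p & ~t))
        fn = int(np.sum(~p & t))
        tn = int(np.sum(~p & ~t))
        absent = not (p.any() or t.any())
        out[c] = ClassMetrics(
            iou=_ratio(tp, tp + fp + fn, absent),
            accuracy=(tp + tn) / max(tp + tn + fp + fn, 1),
            precision=_ratio(tp, tp + fp, absent),
            recall=_ratio(tp, tp + fn, absent),
        )
    return out
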
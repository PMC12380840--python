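"""Pixel-level evaluation: confusion matrix, pixel accuracy, mean IoU.

The confusion matrix entry ``counts[i, j]`` is the number of pixels whose
true class is ``i`` and predicted class is ``j``.  Pixel accuracy is the
trace over the total count; mean IoU averages, over classes, the ratio of
true positives to the union (row + column - diagonal).  Classes absent from
both prediction and truth (zero union) are excluded from the mean rather
than contributing 0/0.
"""
from __future__ import annotations

import numpy as np


class ConfusionMatrix:
    """Accumulating n x n pixel-count confusion matrix."""

    def __init__(self, num_classes: int, counts: np.ndarray | None = None):
        if num_classes < 2:
            raise ValueError("need at least two classes")
        self.num_classes = num_classes
        if counts is None:
            self.counts = np.zeros((num_classes, num_classes), dtype=np.int64)
        else:
            counts = np.asarray(counts, dtype=np.int64)
            if counts.shape != (num_classes, num_classes) or (counts < 0).any():
                raise ValueError("counts must be a nonnegative n x n matrix")
            self.counts = counts.copy()

    def update(self, true_mask, pred_mask) -> "ConfusionMatrix":
        """Accumulate pixel counts from a pair of integer masks (in place)."""
        t = np.asarray(true_mask).ravel()
        p = np.asarray(pred_mask).ravel()
        if t.shape != p.shape:
            raise ValueError("mask shapes differ")
        n = self.num_classes
        if t.size and (t.min() < 0 or t.max() >= n or p.min() < 0 or p.max() >= n):
            raise ValueError(f"class codes must lie in [0, {n})")
        binned = np.bincount(t.astype(np.int64) * n + p.astype(np.int64),
                             minlength=n * n)
        self.counts += binned.reshape(n, n)
        return self

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        if other.num_classes != self.num_classes:
            raise ValueError("class counts differ")
        return ConfusionMatrix(self.num_classes, self.counts + other.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def update_confusion(cm: ConfusionMatrix, pred_mask, true_mask) -> ConfusionMatrix:
    """Functional form of :meth:`ConfusionMatrix.update`."""
    return cm.update(true_mask, pred_mask)


def _counts(cm) -> np.ndarray:
    return cm.counts if isinstance(cm, ConfusionMatrix) else np.asarray(cm, dtype=np.int64)


def pixel_accuracy(cm) -> float:
    """Trace over total pixel count."""
    c = _counts(cm)
    total = c.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(c) / total)


def mean_iou(cm) -> float:
    """Mean over classes of TP / (row + col - TP); zero-union classes excluded."""
    c = _counts(cm)
    if c.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = np.diag(c).astype(np.float64)
    union = c.sum(axis=1) + c.sum(axis=0) - np.diag(c)
    valid = union > 0
    return float(np.mean(tp[valid] / union[valid]))


def evaluate_masks(true_masks, pred_masks, num_classes: int = 2):
    """Convenience: (PA, MIoU, ConfusionMatrix) over paired mask stacks."""
    cm = ConfusionMatrix(num_classes)
    for t, p in zip(true_masks, pred_masks):
        cm.update(t, p)
    return pixel_accuracy(cm), mean_iou(cm), cm
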
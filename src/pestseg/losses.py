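"""Hybrid segmentation loss: weighted cross-entropy plus soft Dice.

``loss = lambda * CE + (1 - lambda) * Dice`` with ``lambda = 0.4`` and Dice
smoothing ``epsilon = 0.001`` by default.  Cross-entropy is the mean over
pixels of the negative log softmax probability of the true class; Dice is
one minus the soft overlap coefficient computed over all classes and pixels
jointly.  Both accept hard integer masks or probability-valued (soft)
targets, so mixup-style soft labels train without special-casing.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import tensor as T
from .tensor import Tensor


@dataclass
class LossConfig:
    lam: float = 0.4
    epsilon: float = 1e-3
    num_classes: int = 2

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.num_classes < 2:
            raise ValueError("need at least two classes")


def one_hot(target: np.ndarray, num_classes: int) -> np.ndarray:
    """Integer class codes -> one-hot float array with a trailing class axis."""
    target = np.asarray(target)
    if target.min() < 0 or target.max() >= num_classes:
        raise ValueError(
            f"class codes must lie in [0, {num_classes}); "
            f"got range [{target.min()}, {target.max()}]")
    return np.eye(num_classes)[target]


def _target_probs(target, num_classes: int) -> np.ndarray:
    """Accept hard integer masks or soft probability targets."""
    target = np.asarray(target)
    if np.issubdtype(target.dtype, np.integer):
        return one_hot(target, num_classes)
    if target.shape[-1] != num_classes:
        raise ValueError("soft targets must carry a trailing class axis")
    return target.astype(np.float64)


def dice_loss(probs, target, eps: float = 1e-3) -> Tensor:
    """Soft Dice loss: 1 - 2|P∩Y| / (|P| + |Y| + eps), summed over classes
    and pixels jointly.  ``probs`` are per-pixel class probabilities with a
    trailing class axis; ``target`` is one-hot (or soft) with the same shape.
    """
    probs = T.as_tensor(probs)
    y = np.asarray(target, dtype=np.float64)
    if probs.shape != y.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape} vs target {y.shape}")
    inter = (probs * y).sum()
    denom = probs.sum() + float(y.sum()) + eps
    return 1.0 - 2.0 * inter / denom


def ce_loss(logits, target, num_classes: int | None = None) -> Tensor:
    """Mean per-pixel cross-entropy from raw logits (trailing class axis)."""
    logits = T.as_tensor(logits)
    n = logits.shape[-1] if num_classes is None else num_classes
    y = _target_probs(target, n)
    if y.shape != logits.shape:
        raise ValueError(f"shape mismatch: logits {logits.shape} vs target {y.shape}")
    logp = T.log_softmax(logits, axis=-1)
    n_pixels = logits.size // n
    return -(logp * y).sum() * (1.0 / n_pixels)


def hybrid_loss(logits, target, cfg: LossConfig | None = None) -> Tensor:
    """``lam * CE + (1 - lam) * Dice`` on softmax probabilities."""
    cfg = cfg or LossConfig()
    logits = T.as_tensor(logits)
    ce = ce_loss(logits, target, cfg.num_classes)
    probs = T.softmax(logits, axis=-1)
    y = _target_probs(target, cfg.num_classes)
    dice = dice_loss(probs, y, cfg.epsilon)
    return cfg.lam * ce + (1.0 - cfg.lam) * dice
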
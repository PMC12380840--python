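"""Training protocol: SGD with momentum, periodic validation, best-checkpointing.

The published protocol trains with stochastic gradient descent (momentum
0.9, weight decay 1e-4, constant learning rate 1e-3, batch size 24) for
3,000 iterations, evaluates PA and mean IoU on the validation subset every
200 iterations, and persists weights only when validation performance
strictly improves.  Mean IoU is the selection metric, with PA as the
tie-break.  All randomness (batch sampling) is driven by the configured
seed.
"""
from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import tensor as T
from .losses import LossConfig, hybrid_loss
from .metrics import ConfusionMatrix, pixel_accuracy, mean_iou


@dataclass
class TrainConfig:
    iterations: int = 3000
    batch_size: int = 24
    learning_rate: float = 1e-3
    momentum: float = 0.9
    weight_decay: float = 1e-4
    eval_every: int = 200
    seed: int = 0

    def __post_init__(self):
        if min(self.iterations, self.batch_size, self.eval_every) < 1:
            raise ValueError("iterations, batch size and eval period must be positive")
        if self.learning_rate < 0 or self.momentum < 0 or self.weight_decay < 0:
            raise ValueError("optimizer settings must be nonnegative")


class SGD:
    """Plain SGD with classical momentum and decoupled-from-nothing weight decay
    (decay is added to the gradient, the standard SGD formulation)."""

    def __init__(self, params, lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v

    def zero_grad(self):
        for p in self.params:
            p.grad = None


@dataclass
class EvalRecord:
    iteration: int
    loss: float
    pixel_accuracy: float
    mean_iou: float


def evaluate_model(model, images: np.ndarray, masks: np.ndarray,
                   num_classes: int = 2, batch_size: int = 8):
    """PA / MIoU of a model over an image/mask stack (single accumulated CM)."""
    cm = ConfusionMatrix(num_classes)
    for s in range(0, len(images), batch_size):
        pred = model.predict_mask(images[s:s + batch_size])
        cm.update(masks[s:s + batch_size], pred)
    return pixel_accuracy(cm), mean_iou(cm), cm


def train(model, train_images, train_masks, val_images=None, val_masks=None,
          train_config: TrainConfig | None = None,
          loss_config: LossConfig | None = None,
          callback=None, batch_augment=None):
    """Run the protocol; return (history, best_state, best_record, losses).

    ``history`` is a list of :class:`EvalRecord` (one per validation pass);
    ``best_state`` the parameter snapshot at the best validation MIoU
    (PA tie-break); ``losses`` the per-iteration training losses.
    ``callback(iteration, loss)`` fires every iteration if provided.
    ``batch_augment(images, masks, rng) -> (images, targets)`` applies
    training-time mixing (e.g. :func:`pestseg.augment.make_batch_mixer`);
    targets may be hard masks or soft probability maps.
    """
    tcfg = train_config or TrainConfig()
    lcfg = loss_config or LossConfig()
    train_images = np.asarray(train_images, dtype=np.float64)
    train_masks = np.asarray(train_masks)
    n_train = len(train_images)
    if n_train == 0:
        raise ValueError("empty training set")
    has_val = val_images is not None and len(val_images) > 0
    rng = np.random.default_rng(tcfg.seed)
    opt = SGD(model.parameters(), tcfg.learning_rate, tcfg.momentum,
              tcfg.weight_decay)
    history: list[EvalRecord] = []
    losses: list[float] = []
    best_state = None
    best_record = None
    for it in range(1, tcfg.iterations + 1):
        idx = rng.choice(n_train, size=min(tcfg.batch_size, n_train), replace=False)
        batch_imgs, batch_targets = train_images[idx], train_masks[idx]
        if batch_augment is not None:
            batch_imgs, batch_targets = batch_augment(batch_imgs,
                                                      batch_targets, rng)
        logits = model.forward(T.Tensor(batch_imgs))
        loss = hybrid_loss(logits, batch_targets, lcfg)
        loss_val = loss.item()
        if not np.isfinite(loss_val):
            raise RuntimeError(f"non-finite loss at iteration {it}: {loss_val}")
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss_val)
        if callback is not None:
            callback(it, loss_val)
        if it % tcfg.eval_every == 0:
            if has_val:
                pa, miou, _ = evaluate_model(model, np.asarray(val_images),
                                             np.asarray(val_masks),
                                             lcfg.num_classes)
            else:
                pa, miou, _ = evaluate_model(model, train_images, train_masks,
                                             lcfg.num_classes)
            rec = EvalRecord(it, float(np.mean(losses[-tcfg.eval_every:])), pa, miou)
            history.append(rec)
            improved = (best_record is None
                        or rec.mean_iou > best_record.mean_iou
                        or (rec.mean_iou == best_record.mean_iou
                            and rec.pixel_accuracy > best_record.pixel_accuracy))
            if improved:
                best_record = rec
                best_state = model.state_dict()
    if best_state is None:  # no evaluation ever ran
        best_state = model.state_dict()
    return history, best_state, best_record, losses


def save_checkpoint(path, state: dict, config_dict: dict, history):
    """Persist weights + architecture config + metric history (npz + json)."""
    import json
    from pathlib import Path

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **state)
    meta = {
        "config": config_dict,
        "history": [asdict(h) for h in history],
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path):
    """Return (state dict, meta dict) written by :func:`save_checkpoint`."""
    import json
    from pathlib import Path

    path = Path(path)
    with np.load(path) as data:
        state = {k: data[k] for k in data.files}
    meta = json.loads(path.with_suffix(".json").read_text())
    return state, meta
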
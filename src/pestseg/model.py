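"""High-level modelling interface: :class:`PestSegmenter` and :class:`FitResults`.

The segmenter wraps the network and the training protocol behind a
fit/results API: build the model from a configuration, call
:meth:`PestSegmenter.fit` on paired image/mask arrays, and receive a
:class:`FitResults` carrying the best weights, the validation history, and
a :meth:`FitResults.summary` table.  Prediction, evaluation, plotting and
checkpointing hang off these two objects.
"""
from __future__ import annotations

from dataclasses import asdict

import numpy as np
import pandas as pd

from .data import images_to_float
from .losses import LossConfig
from .metrics import pixel_accuracy, mean_iou  # re-exported convenience
from .network import ModelConfig, PestSegNet
from .training import (TrainConfig, train, evaluate_model,
                       save_checkpoint, load_checkpoint)


class PestSegmenter:
    """Vision-Mamba U-Net segmentation model with a fit/results workflow."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.network = PestSegNet(self.config)

    @classmethod
    def from_config_dict(cls, d: dict) -> "PestSegmenter":
        return cls(ModelConfig.from_dict(d))

    @property
    def num_parameters(self) -> int:
        return self.network.num_parameters()

    def fit(self, images, masks, val_images=None, val_masks=None,
            train_config: TrainConfig | None = None,
            loss_config: LossConfig | None = None,
            callback=None) -> "FitResults":
        """Train on uint8 (or [0,1] float) images and {0,1} integer masks."""
        imgs = images_to_float(images) if np.asarray(images).dtype == np.uint8 \
            else np.asarray(images, dtype=np.float64)
        v_imgs = None
        if val_images is not None and len(val_images):
            v_imgs = images_to_float(val_images) \
                if np.asarray(val_images).dtype == np.uint8 \
                else np.asarray(val_images, dtype=np.float64)
        tcfg = train_config or TrainConfig()
        lcfg = loss_config or LossConfig(num_classes=self.config.num_classes)
        history, best_state, best_record, losses = train(
            self.network, imgs, np.asarray(masks), v_imgs,
            None if val_masks is None else np.asarray(val_masks),
            tcfg, lcfg, callback=callback)
        return FitResults(self, history, best_state, best_record, losses, tcfg, lcfg)

    def predict(self, images) -> np.ndarray:
        """Hard {0,..,n-1} masks for uint8 or [0,1] float images."""
        imgs = images_to_float(images) if np.asarray(images).dtype == np.uint8 \
            else np.asarray(images, dtype=np.float64)
        return self.network.predict_mask(imgs)

    def predict_proba(self, images) -> np.ndarray:
        imgs = images_to_float(images) if np.asarray(images).dtype == np.uint8 \
            else np.asarray(images, dtype=np.float64)
        return self.network.predict_proba(imgs)

    def evaluate(self, images, masks):
        """(PA, MIoU, confusion matrix) on a labelled set."""
        imgs = images_to_float(images) if np.asarray(images).dtype == np.uint8 \
            else np.asarray(images, dtype=np.float64)
        return evaluate_model(self.network, imgs, np.asarray(masks),
                              self.config.num_classes)

    def save(self, path, history=()):
        save_checkpoint(path, self.network.state_dict(),
                        self.config.to_dict(), list(history))

    @classmethod
    def load(cls, path) -> "PestSegmenter":
        state, meta = load_checkpoint(path)
        model = cls.from_config_dict(meta["config"])
        model.network.load_state_dict(state)
        return model


class FitResults:
    """Outcome of a training run: history, best weights, summary, plots."""

    def __init__(self, model: PestSegmenter, history, best_state,
                 best_record, losses, train_config, loss_config):
        self.model = model
        self.history = history
        self.best_state = best_state
        self.best_record = best_record
        self.losses = list(losses)
        self.train_config = train_config
        self.loss_config = loss_config

    @property
    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(h) for h in self.history])

    @property
    def best_miou(self) -> float:
        return self.best_record.mean_iou if self.best_record else float("nan")

    @property
    def best_pa(self) -> float:
        return self.best_record.pixel_accuracy if self.best_record else float("nan")

    def restore_best(self) -> PestSegmenter:
        """Load the best-validation weights back into the model."""
        self.model.network.load_state_dict(self.best_state)
        return self.model

    def save(self, path):
        save_checkpoint(path, self.best_state, self.model.config.to_dict(),
                        self.history)

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Pest segmentation fit",
            "=" * 52,
            f"{'base channels (C)':32s}{cfg.base_channels:>16d}",
            f"{'encoder depths':32s}{str(tuple(cfg.encoder_depths)):>16s}",
            f"{'parameters':32s}{self.model.num_parameters:>16,d}",
            f"{'iterations':32s}{self.train_config.iterations:>16d}",
            f"{'batch size':32s}{self.train_config.batch_size:>16d}",
            f"{'learning rate':32s}{self.train_config.learning_rate:>16.4g}",
            f"{'loss lambda (CE weight)':32s}{self.loss_config.lam:>16.2f}",
            f"{'final training loss':32s}"
            f"{(self.losses[-1] if self.losses else float('nan')):>16.4f}",
            f"{'evaluations run':32s}{len(self.history):>16d}",
            f"{'best PA':32s}{self.best_pa:>16.4f}",
            f"{'best MIoU':32s}{self.best_miou:>16.4f}",
            "=" * 52,
        ]
        return "\n".join(lines)

    def plot_history(self, path=None):
        """Loss / PA / MIoU curves over evaluation checkpoints."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.2))
        ax1.plot(np.arange(1, len(self.losses) + 1), self.losses, lw=0.8)
        ax1.set_xlabel("iteration")
        ax1.set_ylabel("hybrid loss")
        hf = self.history_frame
        if len(hf):
            ax2.plot(hf.iteration, hf.pixel_accuracy, marker="o", label="PA")
            ax2.plot(hf.iteration, hf.mean_iou, marker="s", label="MIoU")
            ax2.set_xlabel("iteration")
            ax2.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig
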
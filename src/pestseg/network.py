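"""The full segmentation network: a symmetric vision-Mamba U-Net.

Topology for an ``H x W x 3`` input (H, W divisible by 32), base width C:

* patch embedding: non-overlapping 4x4 patches -> [H/4, W/4, C] tokens + LN
* encoder: four stages of stacked multiscale VSS blocks, with patch merging
  between stages; stage resolutions H/4 x C, H/8 x 2C, H/16 x 4C, H/32 x 8C
* bottleneck: multiscale attention aggregation on the deepest stage
* decoder: four stages of stacked VSS blocks with patch expanding; each
  stage adds the channel-aware attentive skip of the matching encoder stage
* head: 4x patch expansion back to full resolution, 1x1 convolution to
  per-pixel class logits (softmax is applied only at prediction time)
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import tensor as T
from .nn import Module, Linear, LayerNorm, Conv2d
from .ssm import SS2DConfig
from .blocks import (VSSBlockConfig, MSDCConfig, MSAAConfig,
                     VSSBlock, MultiScaleVSSBlock, MSAABottleneck, AttentiveSkip)
from .tensor import Tensor


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``base_channels`` is the token width C of the first stage (the published
    configuration uses 96); stages widen as C, 2C, 4C, 8C.  ``use_msvss``,
    ``use_msaa`` and ``use_cavss`` are ablation switches: disabling them
    falls back to plain VSS encoder blocks, a pass-through bottleneck and
    plain additive skips respectively.
    """

    base_channels: int = 96
    patch_size: int = 4
    encoder_depths: tuple = (2, 2, 2, 2)
    decoder_depths: tuple = (2, 2, 2, 2)
    num_classes: int = 2
    state_size: int = 16
    expand_ratio: int = 2
    se_reduction: int = 4
    dw_kernel: int = 3
    msdc_kernels: tuple = (1, 3, 5)
    msaa_rates: tuple = (1, 3, 5)
    msaa_gate_kernel: int = 7
    cavss_gate_kernel: int = 3
    use_msvss: bool = True
    use_msaa: bool = True
    use_cavss: bool = True
    zero_init_residual: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.base_channels % 2 != 0:
            raise ValueError("base channels must be even")
        if self.num_classes < 2:
            raise ValueError("need at least two classes")
        if len(self.encoder_depths) != 4 or len(self.decoder_depths) != 4:
            raise ValueError("exactly four encoder and four decoder stages")

    @property
    def stride(self) -> int:
        # patch embedding (4x) plus three 2x merges
        return self.patch_size * 8

    def vss_config(self, channels: int) -> VSSBlockConfig:
        return VSSBlockConfig(
            channels=channels, expand_ratio=self.expand_ratio,
            se_reduction=self.se_reduction, dw_kernel=self.dw_kernel,
            ssm=SS2DConfig(state_size=self.state_size),
            zero_init_residual=self.zero_init_residual)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("encoder_depths", "decoder_depths", "msdc_kernels", "msaa_rates"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("encoder_depths", "decoder_depths", "msdc_kernels", "msaa_rates"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


class PatchEmbed(Module):
    """Linear embedding of non-overlapping p x p patches, then layer norm."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        p = cfg.patch_size
        self.patch = p
        self.proj = Linear(p * p * 3, cfg.base_channels, rng)
        self.norm = LayerNorm(cfg.base_channels)

    def forward(self, img: Tensor) -> Tensor:
        B, H, W, C = img.shape
        p = self.patch
        if H % p or W % p:
            raise ValueError(f"image size {H}x{W} not divisible by patch size {p}")
        x = img.reshape(B, H // p, p, W // p, p, C)
        x = x.transpose(0, 1, 3, 2, 4, 5).reshape(B, H // p, W // p, p * p * C)
        return self.norm(self.proj(x))


class PatchMerge(Module):
    """2x downsampling: concatenate each 2x2 cell (4D channels), LN, linear to 2D.

    Concatenation order is fixed: top-left, top-right, bottom-left,
    bottom-right.
    """

    def __init__(self, dim: int, rng: np.random.Generator):
        self.norm = LayerNorm(4 * dim)
        self.reduce = Linear(4 * dim, 2 * dim, rng, bias=False)

    def forward(self, x: Tensor) -> Tensor:
        B, H, W, D = x.shape
        if H % 2 or W % 2:
            raise ValueError(f"spatial size {H}x{W} must be even to merge")
        x = x.reshape(B, H // 2, 2, W // 2, 2, D)
        x = x.transpose(0, 1, 3, 2, 4, 5)          # [B, H/2, W/2, 2, 2, D]
        x = x.reshape(B, H // 2, W // 2, 4 * D)    # cell order TL, TR, BL, BR
        return self.reduce(self.norm(x))


class PatchExpand(Module):
    """2x upsampling: linear to 2D channels, rearranged into 2x2 cells of D/2."""

    def __init__(self, dim: int, rng: np.random.Generator):
        if dim % 2:
            raise ValueError("channel count must be even to expand")
        self.expand = Linear(dim, 2 * dim, rng, bias=False)
        self.norm = LayerNorm(dim // 2)

    def forward(self, x: Tensor) -> Tensor:
        B, H, W, D = x.shape
        y = self.expand(x)                          # [B, H, W, 2D]
        y = y.reshape(B, H, W, 2, 2, D // 2)
        y = y.transpose(0, 1, 3, 2, 4, 5).reshape(B, 2 * H, 2 * W, D // 2)
        return self.norm(y)


class FinalExpand(Module):
    """4x expansion back to pixel resolution, then a 1x1 convolution head."""

    def __init__(self, dim: int, num_classes: int, rng: np.random.Generator):
        self.expand = Linear(dim, 16 * dim, rng, bias=False)
        self.norm = LayerNorm(dim)
        self.head = Conv2d(dim, num_classes, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        B, H, W, D = x.shape
        y = self.expand(x).reshape(B, H, W, 4, 4, D)
        y = y.transpose(0, 1, 3, 2, 4, 5).reshape(B, 4 * H, 4 * W, D)
        return self.head(self.norm(y))


class _Passthrough(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class PestSegNet(Module):
    """Symmetric encoder-decoder with state-space blocks and attentive skips."""

    def __init__(self, config: ModelConfig | None = None,
                 rng: np.random.Generator | None = None):
        config = config or ModelConfig()
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.config = config
        C = config.base_channels
        widths = [C, 2 * C, 4 * C, 8 * C]
        self.stage_widths = widths
        msdc = MSDCConfig(config.msdc_kernels)

        self.embed = PatchEmbed(config, rng)
        self.encoder_stages = []
        for s, depth in enumerate(config.encoder_depths):
            blocks = []
            for _ in range(depth):
                if config.use_msvss:
                    blocks.append(MultiScaleVSSBlock(
                        config.vss_config(widths[s]), msdc, rng))
                else:
                    blocks.append(VSSBlock(config.vss_config(widths[s]), rng))
            self.encoder_stages.append(blocks)
        self.merges = [PatchMerge(widths[s], rng) for s in range(3)]

        if config.use_msaa:
            self.bottleneck = MSAABottleneck(
                widths[3], MSAAConfig(config.msaa_rates, config.msaa_gate_kernel), rng)
        else:
            self.bottleneck = _Passthrough()

        if config.use_cavss:
            self.skips = [AttentiveSkip(config.vss_config(widths[s]), rng,
                                        gate_kernel=config.cavss_gate_kernel)
                          for s in range(4)]
        else:
            self.skips = [_Passthrough() for _ in range(4)]

        self.decoder_stages = []
        for s, depth in enumerate(config.decoder_depths):
            w = widths[3 - s]
            self.decoder_stages.append(
                [VSSBlock(config.vss_config(w), rng) for _ in range(depth)])
        self.expands = [PatchExpand(widths[3 - s], rng) for s in range(3)]
        self.final = FinalExpand(C, config.num_classes, rng)

    # ------------------------------------------------------------- plumbing
    def _check_input(self, img: Tensor):
        if img.ndim != 4 or img.shape[-1] != 3:
            raise ValueError("input must be [B, H, W, 3]")
        _, H, W, _ = img.shape
        s = self.config.stride
        if H % s or W % s:
            raise ValueError(
                f"input size {H}x{W} must be divisible by {s} "
                f"(patch size {self.config.patch_size} with three 2x merges)")

    def encode(self, img: Tensor):
        """Return the four encoder stage outputs (the skip features)."""
        self._check_input(img)
        x = self.embed(img)
        feats = []
        for s in range(4):
            for block in self.encoder_stages[s]:
                x = block(x)
            feats.append(x)
            if s < 3:
                x = self.merges[s](x)
        return feats

    def decode(self, feats):
        """Run bottleneck + decoder over encoder features; return stage outputs."""
        d = self.bottleneck(feats[3]) + self.skips[3](feats[3])
        outs = []
        for s in range(4):
            for block in self.decoder_stages[s]:
                d = block(d)
            outs.append(d)
            if s < 3:
                d = self.expands[s](d)
                d = d + self.skips[2 - s](feats[2 - s])
        return outs

    def forward(self, img: Tensor) -> Tensor:
        """Per-pixel class logits [B, H, W, num_classes]."""
        img = T.as_tensor(img)
        feats = self.encode(img)
        outs = self.decode(feats)
        return self.final(outs[-1])

    def predict_proba(self, img) -> np.ndarray:
        """Softmax class probabilities (inference mode, no tape)."""
        with T.no_grad():
            logits = self.forward(T.as_tensor(img))
        return T.softmax(logits, axis=-1).data

    def predict_mask(self, img) -> np.ndarray:
        """Hard per-pixel class codes [B, H, W]."""
        return np.argmax(self.predict_proba(img), axis=-1)
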
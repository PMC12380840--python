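"""Composite blocks of the segmentation network.

* :class:`DWConv` — depthwise-separable convolution (depthwise + pointwise).
* :class:`SEGate` — squeeze-and-excitation channel gate.
* :class:`VSSBlock` — visual state-space block: LN, linear expansion,
  depthwise-separable convolution with SiLU, SS2D, SE gate, LN, linear
  projection back, residual.
* :class:`MSDC` — parallel multi-kernel (1/3/5) convolutions, summed and
  fused by a 1x1 convolution.
* :class:`MultiScaleVSSBlock` — VSS followed by a linear projection and an
  MSDC with a second residual (the encoder's workhorse block).
* :class:`MSAABottleneck` — multiscale attention aggregation: dilated
  convolutions (rates 1/3/5) under a spatial sigmoid gate built from
  channelwise average/max maps.
* :class:`AttentiveSkip` — channel-aware attentional skip connection: a VSS
  block whose normalised, convolved output is modulated by a pooled-map
  sigmoid gate and added back to the VSS output.

Residual projections are zero-initialised so every block is an exact
identity (or residual passthrough) at initialisation, which keeps deep
stacks trainable from the first step.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import tensor as T
from .nn import Module, Linear, LayerNorm, Conv2d, DepthwiseConv2d
from .ssm import SS2D, SS2DConfig
from .tensor import Tensor


@dataclass
class VSSBlockConfig:
    channels: int
    expand_ratio: int = 2
    se_reduction: int = 4
    dw_kernel: int = 3
    ssm: SS2DConfig = field(default_factory=SS2DConfig)
    # zero/identity residual projections make blocks the identity at init;
    # switch off for generic-init gradient-flow checks
    zero_init_residual: bool = True

    def __post_init__(self):
        if min(self.channels, self.expand_ratio, self.se_reduction) < 1:
            raise ValueError("VSS config fields must be positive")
        if self.dw_kernel % 2 == 0:
            raise ValueError("depthwise kernel must be odd")


@dataclass
class MSDCConfig:
    kernel_sizes: tuple = (1, 3, 5)

    def __post_init__(self):
        if any(k % 2 == 0 for k in self.kernel_sizes):
            raise ValueError("kernel sizes must be odd")


@dataclass
class MSAAConfig:
    dilation_rates: tuple = (1, 3, 5)
    gate_kernel: int = 7

    def __post_init__(self):
        if any(r < 1 for r in self.dilation_rates):
            raise ValueError("dilation rates must be positive")
        if self.gate_kernel % 2 == 0:
            raise ValueError("gate kernel must be odd")


class DWConv(Module):
    """Depthwise-separable convolution: per-channel k x k then pointwise 1x1."""

    def __init__(self, channels: int, k: int, rng: np.random.Generator):
        if k % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {k}")
        self.depthwise = DepthwiseConv2d(channels, k, rng)
        self.pointwise = Conv2d(channels, channels, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))


class SEGate(Module):
    """Squeeze-and-excitation: GAP -> bottleneck MLP -> sigmoid channel weights."""

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        if reduction < 1:
            raise ValueError("reduction must be >= 1")
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)

    def forward(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(1, 2))                  # [B, C]
        w = T.sigmoid(self.fc2(T.relu(self.fc1(pooled))))
        return x * w.reshape(w.shape[0], 1, 1, w.shape[1])


def _spatial_gate_input(x: Tensor) -> Tensor:
    """Channelwise average and max maps stacked to a 2-channel map."""
    avg = x.mean(axis=-1, keepdims=True)
    mx = T.tmax(x, axis=-1, keepdims=True)
    return T.concatenate([avg, mx], axis=-1)


class VSSBlock(Module):
    """Visual state-space block with pre-norm residual form."""

    def __init__(self, cfg: VSSBlockConfig, rng: np.random.Generator):
        self.cfg = cfg
        d, e = cfg.channels, cfg.channels * cfg.expand_ratio
        self.norm_in = LayerNorm(d)
        self.expand = Linear(d, e, rng)
        self.dwconv = DWConv(e, cfg.dw_kernel, rng)
        self.ss2d = SS2D(e, rng, cfg.ssm)
        self.se = SEGate(e, cfg.se_reduction, rng)
        self.norm_out = LayerNorm(e)
        proj_init = "zeros" if cfg.zero_init_residual else "trunc_normal"
        self.project = Linear(e, d, rng, init=proj_init)

    def forward(self, x: Tensor) -> Tensor:
        h = self.expand(self.norm_in(x))
        h = T.silu(self.dwconv(h))
        h = self.ss2d(h)
        h = self.se(h)
        h = self.project(self.norm_out(h))
        return h + x


class MSDC(Module):
    """Multi-kernel convolution set: parallel 1/3/5 branches, summed, 1x1 fused."""

    def __init__(self, channels: int, cfg: MSDCConfig, rng: np.random.Generator,
                 zero_init_fuse: bool = True):
        self.cfg = cfg
        self.branches = [Conv2d(channels, channels, k, rng)
                         for k in cfg.kernel_sizes]
        self.fuse = Conv2d(channels, channels, 1, rng,
                           init="zeros" if zero_init_fuse else "trunc_normal")

    def forward(self, x: Tensor) -> Tensor:
        acc = None
        for branch in self.branches:
            y = branch(x)
            acc = y if acc is None else acc + y
        return self.fuse(acc)


class MultiScaleVSSBlock(Module):
    """VSS block, linear projection, then multi-kernel refinement with residual.

    The linear projection is identity-initialised and the MSDC fusion
    zero-initialised, so the whole block starts as the identity map.
    """

    def __init__(self, cfg: VSSBlockConfig, msdc_cfg: MSDCConfig,
                 rng: np.random.Generator):
        d = cfg.channels
        self.vss = VSSBlock(cfg, rng)
        proj_init = "identity" if cfg.zero_init_residual else "trunc_normal"
        self.proj = Linear(d, d, rng, init=proj_init)
        self.msdc = MSDC(d, msdc_cfg, rng,
                         zero_init_fuse=cfg.zero_init_residual)

    def forward(self, x: Tensor) -> Tensor:
        u = self.proj(self.vss(x))
        return self.msdc(u) + u


class MSAABottleneck(Module):
    """Multiscale attention aggregation at the deepest encoder resolution.

    A 1x1 projection feeds three parallel 3x3 dilated convolutions (rates
    1/3/5, summed); a single-channel spatial sigmoid gate built from the
    channelwise average/max maps modulates the dilated features; the gated
    map plus the projected input pass through a final 1x1 convolution.
    """

    def __init__(self, channels: int, cfg: MSAAConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.proj_in = Conv2d(channels, channels, 1, rng, init="identity")
        self.dilated = [Conv2d(channels, channels, 3, rng, dilation=r)
                        for r in cfg.dilation_rates]
        self.gate_conv = Conv2d(2, 1, cfg.gate_kernel, rng)
        self.proj_out = Conv2d(channels, channels, 1, rng, init="identity")

    def forward(self, x: Tensor) -> Tensor:
        p = self.proj_in(x)
        fdil = None
        for conv in self.dilated:
            y = conv(p)
            fdil = y if fdil is None else fdil + y
        gate = T.sigmoid(self.gate_conv(_spatial_gate_input(fdil)))
        return self.proj_out(gate * fdil + p)


class AttentiveSkip(Module):
    """Channel-aware attentional skip connection.

    ``v = VSS(x); f = Conv3x3(LN(v)); out = sigmoid-gate(f) * f + v``.
    The 3x3 convolution is zero-initialised, so at init the skip passes the
    VSS output (itself the identity at init) straight through.
    """

    def __init__(self, cfg: VSSBlockConfig, rng: np.random.Generator,
                 gate_kernel: int = 3):
        d = cfg.channels
        self.vss = VSSBlock(cfg, rng)
        self.norm = LayerNorm(d)
        self.conv = Conv2d(d, d, 3, rng,
                           init="zeros" if cfg.zero_init_residual else "trunc_normal")
        self.gate_conv = Conv2d(2, 1, gate_kernel, rng)

    def forward(self, x: Tensor) -> Tensor:
        v = self.vss(x)
        f = self.conv(self.norm(v))
        gate = T.sigmoid(self.gate_conv(_spatial_gate_input(f)))
        return gate * f + v
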
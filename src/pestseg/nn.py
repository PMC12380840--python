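"""Neural-network layers on top of the :mod:`pestseg.tensor` engine.

Layers follow channels-last conventions: feature maps are ``[B, H, W, D]``
and token grids are flattened as needed by the caller.  Convolutions are
stride-1 with symmetric ("same") zero padding — the architecture changes
resolution only through patch merging/expanding, never through strided
convolution.
"""
from __future__ import annotations

import numpy as np

from .tensor import Tensor, accum, make_node


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Truncated-normal init (clipped at two standard deviations).

    The narrow flat scale — rather than fan-in scaling — keeps initial
    logits near zero so the softmax starts uniform; with the identity-at-init
    residual blocks this is what makes short from-scratch SGD runs converge.
    """
    return np.clip(rng.standard_normal(shape) * std, -2.0 * std, 2.0 * std)


class Module:
    """Minimal module container: tracks parameters and sub-modules by attribute."""

    def __setattr__(self, name, value):
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        def walk(name, value):
            if isinstance(value, Tensor) and value.requires_grad:
                yield name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(name)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    yield from walk(f"{name}.{i}", item)

        for name, value in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            yield from walk(full, value)

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict is missing parameters: {sorted(missing)[:5]}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _param(data) -> Tensor:
    return Tensor(data, requires_grad=True)


class Linear(Module):
    """Affine map applied to the last axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 init: str = "trunc_normal", bias: bool = True):
        if init == "zeros":
            w = np.zeros((d_in, d_out))
        elif init == "identity":
            if d_in != d_out:
                raise ValueError("identity init requires square weight")
            w = np.eye(d_in)
        else:
            w = trunc_normal(rng, (d_in, d_out))
        self.weight = _param(w)
        self.bias = _param(np.zeros(d_out)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        self.gamma = _param(np.ones(dim))
        self.beta = _param(np.zeros(dim))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * ((var + self.eps) ** -0.5) * self.gamma + self.beta


def _same_pad(k: int, dilation: int) -> int:
    if k % 2 == 0:
        raise ValueError(f"kernel size must be odd, got {k}")
    return dilation * (k - 1) // 2


def conv2d_op(x: Tensor, weight: Tensor, bias: Tensor | None,
              dilation: int = 1) -> Tensor:
    """Dense stride-1 'same' 2D convolution, channels-last.

    ``x``: [B, H, W, Cin]; ``weight``: [k, k, Cin, Cout].  Implemented as k²
    shifted matmuls, which keeps peak memory proportional to the input.
    """
    k = weight.data.shape[0]
    p = _same_pad(k, dilation)
    B, H, W, Cin = x.data.shape
    Cout = weight.data.shape[3]
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0)))
    out = np.zeros((B * H * W, Cout))
    for i in range(k):
        for j in range(k):
            sl = xp[:, i * dilation:i * dilation + H, j * dilation:j * dilation + W, :]
            out += sl.reshape(-1, Cin) @ weight.data[i, j]
    if bias is not None:
        out += bias.data

    def backward(g):
        g2 = g.reshape(-1, Cout)
        if weight.requires_grad:
            gw = np.empty_like(weight.data)
            for i in range(k):
                for j in range(k):
                    sl = xp[:, i * dilation:i * dilation + H,
                            j * dilation:j * dilation + W, :]
                    gw[i, j] = sl.reshape(-1, Cin).T @ g2
            accum(weight, gw)
        if bias is not None and bias.requires_grad:
            accum(bias, g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    gxp[:, i * dilation:i * dilation + H,
                        j * dilation:j * dilation + W, :] += \
                        (g2 @ weight.data[i, j].T).reshape(B, H, W, Cin)
            accum(x, gxp[:, p:p + H, p:p + W, :])

    parents = (x, weight) if bias is None else (x, weight, bias)
    return make_node(out.reshape(B, H, W, Cout), parents, backward)


def depthwise_conv2d_op(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """Per-channel (depthwise) stride-1 'same' 2D convolution.

    ``weight``: [k, k, C] — one k×k filter per channel.
    """
    k = weight.data.shape[0]
    p = _same_pad(k, 1)
    B, H, W, C = x.data.shape
    xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (0, 0)))
    out = np.zeros((B, H, W, C))
    for i in range(k):
        for j in range(k):
            out += xp[:, i:i + H, j:j + W, :] * weight.data[i, j]
    if bias is not None:
        out += bias.data

    def backward(g):
        if weight.requires_grad:
            gw = np.empty_like(weight.data)
            for i in range(k):
                for j in range(k):
                    gw[i, j] = (xp[:, i:i + H, j:j + W, :] * g).sum(axis=(0, 1, 2))
            accum(weight, gw)
        if bias is not None and bias.requires_grad:
            accum(bias, g.sum(axis=(0, 1, 2)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    gxp[:, i:i + H, j:j + W, :] += g * weight.data[i, j]
            accum(x, gxp[:, p:p + H, p:p + W, :])

    parents = (x, weight) if bias is None else (x, weight, bias)
    return make_node(out, parents, backward)


class Conv2d(Module):
    """Dense stride-1 convolution with symmetric padding (odd kernels only)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 dilation: int = 1, init: str = "trunc_normal", bias: bool = True):
        _same_pad(k, dilation)  # validates odd kernel
        if init == "zeros":
            w = np.zeros((k, k, c_in, c_out))
        elif init == "identity":
            if c_in != c_out:
                raise ValueError("identity init requires c_in == c_out")
            w = np.zeros((k, k, c_in, c_out))
            w[k // 2, k // 2] = np.eye(c_in)
        else:
            w = trunc_normal(rng, (k, k, c_in, c_out))
        self.weight = _param(w)
        self.bias = _param(np.zeros(c_out)) if bias else None
        self.dilation = dilation

    def forward(self, x: Tensor) -> Tensor:
        return conv2d_op(x, self.weight, self.bias, dilation=self.dilation)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, k: int, rng: np.random.Generator,
                 init: str = "trunc_normal", bias: bool = True):
        _same_pad(k, 1)
        if init == "identity":
            w = np.zeros((k, k, channels))
            w[k // 2, k // 2] = 1.0
        elif init == "zeros":
            w = np.zeros((k, k, channels))
        else:
            w = trunc_normal(rng, (k, k, channels))
        self.weight = _param(w)
        self.bias = _param(np.zeros(channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return depthwise_conv2d_op(x, self.weight, self.bias)
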
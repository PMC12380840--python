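"""2D selective-scan state-space machinery (SS2D).

The visual selective scan flattens a feature map along four traversal
directions (row-forward, row-reverse, column-forward, column-reverse), runs
an input-dependent linear state-space recurrence (S6) over each sequence,
folds every scanned sequence back to its spatial layout, and sums the four
resulting maps.

The S6 recurrence follows the standard selective-SSM parameterization:
``A = -exp(A_log)`` guarantees a decaying transition; the per-step inputs
``B_t``, ``C_t`` and the discretization step ``delta_t`` are functions of
the token; zero-order-hold discretization gives ``Abar_t = exp(delta_t A)``
with the Euler simplification ``Bbar_t = delta_t * B_t``:

    h_t = Abar_t * h_{t-1} + Bbar_t x_t,    h_0 = 0
    y_t = C_t . h_t + D_skip * x_t

Two surfaces are provided: a functional numpy API with explicit
:class:`SSMParams` (used for contracts and oracle testing), and the
:class:`SS2D` autodiff layer used inside the network, which batches all
four directions through a single recurrence.  The recurrence is evaluated
sequentially in chunks; the chunk size never affects the result.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import tensor as T
from .nn import Module, _param, trunc_normal
from .tensor import Tensor, accum, make_node, _unbroadcast

DIRECTION_IDS = ("row-forward", "row-reverse", "column-forward", "column-reverse")


# --------------------------------------------------------------- data types
@dataclass
class DirectionalSequences:
    """Flattened scan sequences: ``sequences`` is [K, L, D]."""

    sequences: np.ndarray
    direction_ids: tuple
    height: int
    width: int

    def __post_init__(self):
        self.sequences = np.asarray(self.sequences, dtype=np.float64)
        if self.sequences.ndim != 3:
            raise ValueError("sequences must be [K, L, D]")
        if self.sequences.shape[1] != self.height * self.width:
            raise ValueError("sequence length must equal H*W")


@dataclass
class SSMState:
    """Hidden state of the selective recurrence: ``h`` is [D, N], zero at
    the start of every sequence."""

    h: np.ndarray

    def __post_init__(self):
        self.h = np.asarray(self.h, dtype=np.float64)
        if self.h.ndim != 2:
            raise ValueError("state must be [D, N]")
        if not np.isfinite(self.h).all():
            raise ValueError("state must be finite")

    @classmethod
    def zeros(cls, dim: int, state_size: int) -> "SSMState":
        return cls(np.zeros((dim, state_size)))


@dataclass
class SSMParams:
    """Explicit parameters of one selective-scan pass over a length-L sequence.

    ``A_log`` is the log of the (positive) decay magnitude: the transition
    used is ``A = -exp(A_log)`` so that ``exp(delta * A)`` lies in (0, 1].
    """

    A_log: np.ndarray          # [D, N]
    D_skip: np.ndarray         # [D]
    B: np.ndarray              # [L, N]
    C: np.ndarray              # [L, N]
    delta: np.ndarray          # [L, D]

    def __post_init__(self):
        for name in ("A_log", "D_skip", "B", "C", "delta"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.float64))
        if self.A_log.ndim != 2 or self.A_log.shape[1] < 1:
            raise ValueError("A_log must be [D, N] with N >= 1")


def scan_permutations(height: int, width: int) -> np.ndarray:
    """Index permutations [K, L] of the row-major flattening, one per direction."""
    L = height * width
    row_f = np.arange(L)
    col_f = np.arange(L).reshape(height, width).T.ravel()
    return np.stack([row_f, row_f[::-1], col_f, col_f[::-1]])


_PERM_CACHE: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}


def _cached_perms(height: int, width: int):
    key = (height, width)
    if key not in _PERM_CACHE:
        perms = scan_permutations(height, width)
        inv = np.argsort(perms, axis=1)
        _PERM_CACHE[key] = (perms, inv)
    return _PERM_CACHE[key]


# ----------------------------------------------------------- functional API
def scan_expand(x: np.ndarray) -> DirectionalSequences:
    """Expand an [H, W, D] map into the four directional scan sequences."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3 or x.size == 0:
        raise ValueError("empty input")
    H, W, D = x.shape
    flat = x.reshape(H * W, D)
    perms, _ = _cached_perms(H, W)
    seqs = flat[perms]  # [K, L, D]
    return DirectionalSequences(seqs, DIRECTION_IDS, H, W)


def scan_merge(ys: DirectionalSequences) -> np.ndarray:
    """Inverse-permute each scanned sequence and sum the K maps elementwise."""
    K, L, D = ys.sequences.shape
    if L != ys.height * ys.width:
        raise ValueError("sequence length mismatch with spatial extent")
    _, inv = _cached_perms(ys.height, ys.width)
    merged = np.zeros((L, D))
    for k in range(K):
        merged += ys.sequences[k][inv[k]]
    return merged.reshape(ys.height, ys.width, D)


def _scan_core(x, delta, A, Bseq, Cseq, keep_states: bool, chunk: int = 512):
    """Sequential recurrence over arbitrary leading batch dims.

    ``x``/``delta``: [..., L, D]; ``Bseq``/``Cseq``: [..., L, N];
    ``A`` broadcastable to [..., D, N].  Returns (y [..., L, D] without the
    skip term, stacked hidden states [L, ..., D, N] or None).  The loop is
    chunked for cache friendliness; chunking never changes the values.
    """
    L, D = x.shape[-2], x.shape[-1]
    N = Bseq.shape[-1]
    batch = x.shape[:-2]
    # time-major views: cheap per-step slicing
    xT = np.moveaxis(x, -2, 0)          # [L, ..., D]
    dT = np.moveaxis(delta, -2, 0)
    BT = np.moveaxis(Bseq, -2, 0)       # [L, ..., N]
    CT = np.moveaxis(Cseq, -2, 0)
    h = np.zeros(batch + (D, N))
    yT = np.empty((L,) + batch + (D,))
    hs_all = np.empty((L,) + batch + (D, N)) if keep_states else None
    for s in range(0, L, chunk):
        e = min(s + chunk, L)
        abar = np.exp(dT[s:e, ..., None] * A)                       # [l,...,D,N]
        u = dT[s:e, ..., None] * BT[s:e, ..., None, :] * xT[s:e, ..., None]
        hs = hs_all[s:e] if keep_states else np.empty_like(abar)
        for t in range(e - s):
            ht = hs[t]
            np.multiply(abar[t], h, out=ht)
            ht += u[t]
            h = ht
        yT[s:e] = np.einsum("l...dn,l...n->l...d", hs, CT[s:e])
    return np.moveaxis(yT, 0, -2), hs_all


def selective_scan(seq: np.ndarray, params: SSMParams) -> np.ndarray:
    """Run the S6 recurrence over one [L, D] sequence with explicit params."""
    seq = np.asarray(seq, dtype=np.float64)
    if seq.ndim != 2 or seq.shape[0] < 1:
        raise ValueError("sequence must be [L, D] with L >= 1")
    L, D = seq.shape
    if params.delta.shape != (L, D):
        raise ValueError(f"delta must have shape {(L, D)}")
    if np.any(params.delta <= 0):
        raise ValueError("invalid discretization step")
    A = -np.exp(params.A_log)
    y, _ = _scan_core(seq[None], params.delta[None], A,
                      params.B[None], params.C[None], keep_states=False)
    return y[0] + params.D_skip * seq


def ss2d(x: np.ndarray, params: Sequence[SSMParams]) -> np.ndarray:
    """Functional SS2D: expand, scan each direction with its own params, merge."""
    seqs = scan_expand(x)
    K = seqs.sequences.shape[0]
    if len(params) != K:
        raise ValueError(f"expected {K} parameter sets, got {len(params)}")
    outs = np.stack([selective_scan(seqs.sequences[k], params[k]) for k in range(K)])
    return scan_merge(DirectionalSequences(outs, seqs.direction_ids,
                                           seqs.height, seqs.width))


# ------------------------------------------------------- autodiff primitive
def selective_scan_op(u: Tensor, delta: Tensor, A: Tensor,
                      Bseq: Tensor, Cseq: Tensor, Dskip: Tensor,
                      chunk: int = 512) -> Tensor:
    """Differentiable selective scan.

    Shapes as in :func:`_scan_core`; ``A`` and ``Dskip`` may carry broadcast
    (singleton) batch axes.  Backward runs the adjoint recurrence in reverse
    time (also chunked; chunking never changes values).
    """
    need_grad = T.grad_enabled() and any(
        t.requires_grad for t in (u, delta, A, Bseq, Cseq, Dskip))
    y_core, hsT = _scan_core(u.data, delta.data, A.data, Bseq.data, Cseq.data,
                             keep_states=need_grad, chunk=chunk)
    out = y_core + Dskip.data * u.data

    def backward(g):
        L, D = u.data.shape[-2], u.data.shape[-1]
        batch = u.data.shape[:-2]
        gT = np.moveaxis(g, -2, 0)
        xT = np.moveaxis(u.data, -2, 0)
        dT = np.moveaxis(delta.data, -2, 0)
        BT = np.moveaxis(Bseq.data, -2, 0)
        CT = np.moveaxis(Cseq.data, -2, 0)
        accum(Dskip, _unbroadcast(g * u.data, Dskip.data.shape))
        gC_T = np.einsum("l...d,l...dn->l...n", gT, hsT)
        gxT = gT * np.moveaxis(np.broadcast_to(Dskip.data, u.data.shape), -2, 0)
        gdT = np.empty_like(dT)
        gBT = np.empty_like(BT)
        gA = np.zeros(batch + (D, Bseq.data.shape[-1]))
        carry = np.zeros_like(gA)  # a_{t+1} * Abar_{t+1} across chunks
        for s in reversed(range(0, L, chunk)):
            e = min(s + chunk, L)
            abar = np.exp(dT[s:e, ..., None] * A.data)
            dterm = gT[s:e, ..., None] * CT[s:e, ..., None, :]
            a = np.empty_like(abar)
            for t in reversed(range(e - s)):
                np.add(dterm[t], carry, out=a[t])
                carry = a[t] * abar[t]
            h_prev = np.empty_like(abar)
            h_prev[1:] = hsT[s:e - 1]
            h_prev[0] = hsT[s - 1] if s > 0 else 0.0
            m = a * h_prev * abar                      # d/d(delta*A) pathway
            eterm = np.einsum("l...dn,l...n->l...d", a, BT[s:e])
            gdT[s:e] = np.einsum("l...dn,...dn->l...d",
                                 m, np.broadcast_to(A.data, gA.shape)) \
                + eterm * xT[s:e]
            gA += np.einsum("l...dn,l...d->...dn", m, dT[s:e])
            gBT[s:e] = np.einsum("l...dn,l...d->l...n", a, dT[s:e] * xT[s:e])
            gxT[s:e] += eterm * dT[s:e]
        accum(u, np.moveaxis(gxT, 0, -2))
        accum(delta, np.moveaxis(gdT, 0, -2))
        accum(A, _unbroadcast(gA, A.data.shape))
        accum(Bseq, np.moveaxis(gBT, 0, -2))
        accum(Cseq, np.moveaxis(gC_T, 0, -2))

    return make_node(out, (u, delta, A, Bseq, Cseq, Dskip), backward)


# --------------------------------------------------------------- SS2D layer
@dataclass
class SS2DConfig:
    state_size: int = 16
    directions: int = 4
    tie_directions: bool = False
    merge: str = "sum"          # "sum" or "mean"
    dt_min: float = 1e-3
    dt_max: float = 0.1


def gather_perm(a: Tensor, idx: np.ndarray, axis: int) -> Tensor:
    """Gather along ``axis`` with a per-slice permutation index ``idx``
    (shape broadcastable against ``a`` with np.take_along_axis).  Because the
    index is a permutation, the backward scatter has no collisions."""
    a = T.as_tensor(a)
    out_data = np.take_along_axis(a.data, idx, axis=axis)

    def backward(g):
        ga = np.zeros_like(a.data)
        np.put_along_axis(ga, np.broadcast_to(idx, g.shape), g, axis=axis)
        accum(a, ga)

    return make_node(out_data, (a,), backward)


class SS2D(Module):
    """Autodiff SS2D layer: per-direction input-dependent S6 over [B, H, W, D].

    All four directional scans run as one batched recurrence.  ``B_t`` and
    ``C_t`` come from a per-direction linear map of the token; ``delta_t``
    from a linear map passed through softplus, its bias drawn so the initial
    steps land inside [dt_min, dt_max] (standard Mamba-style init).
    ``A_log`` is initialised to ``log(1..N)`` and the skip ``D`` to one.
    With ``tie_directions`` a single parameter set is shared by broadcasting.
    """

    def __init__(self, dim: int, rng: np.random.Generator,
                 cfg: SS2DConfig | None = None):
        cfg = cfg or SS2DConfig()
        if cfg.directions != 4:
            raise ValueError("the visual scan uses the 4 canonical directions")
        self.cfg = cfg
        self.dim = dim
        N = cfg.state_size
        G = 1 if cfg.tie_directions else cfg.directions
        # stacked per-direction parameters with a broadcast batch axis:
        # weights [G, 1, D, out], biases/skips [G, 1, 1, D], A_log [G, 1, D, N]
        self.bc_weight = _param(trunc_normal(rng, (G, 1, dim, 2 * N)))
        self.dt_weight = _param(trunc_normal(rng, (G, 1, dim, dim)))
        dt = np.exp(rng.uniform(np.log(cfg.dt_min), np.log(cfg.dt_max),
                                (G, 1, 1, dim)))
        self.dt_bias = _param(dt + np.log(-np.expm1(-dt)))  # inverse softplus
        self.A_log = _param(np.broadcast_to(
            np.log(np.arange(1, N + 1, dtype=np.float64)),
            (G, 1, dim, N)).copy())
        self.D_skip = _param(np.ones((G, 1, 1, dim)))

    def forward(self, x: Tensor) -> Tensor:
        Bb, H, W, D = x.shape
        if D != self.dim:
            raise ValueError(f"expected {self.dim} channels, got {D}")
        K = self.cfg.directions
        N = self.cfg.state_size
        perms, inv = _cached_perms(H, W)
        flat = x.reshape(Bb, H * W, D)
        # [B, L, D] -> [K, B, L, D] permuted per direction
        seqs = T.take_rows(flat, perms, axis=1).transpose(1, 0, 2, 3)
        delta = T.softplus(seqs @ self.dt_weight + self.dt_bias)
        bc = seqs @ self.bc_weight
        bmat = bc[..., :N]
        cmat = bc[..., N:]
        A = -T.exp(self.A_log)
        y = selective_scan_op(seqs, delta, A, bmat, cmat, self.D_skip)
        y = gather_perm(y, inv[:, None, :, None], axis=2)
        merged = y.sum(axis=0)
        if self.cfg.merge == "mean":
            merged = merged * (1.0 / K)
        return merged.reshape(Bb, H, W, D)
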
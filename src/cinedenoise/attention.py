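"""Decomposed spatiotemporal attention operators for 5D image series.

Full attention over a 2D+T series is quadratic in the number of pixels.
This module decomposes it into three linear-complexity operators acting on
a ``[B, C, F, H, W]`` tensor (batch, channels, frames, height, width):

* **local** attention — among the ``P = (w/p)^2`` patches of each ``w×w``
  window of a frame (captures neighbourhood structure);
* **global** attention — among the ``N = (H/w)(W/w)`` same-position patches
  gathered across all windows of a frame (captures long-range structure);
* **frame** attention — among whole frames along the F axis (captures
  temporal correlation, e.g. across cardiac phases).

Tokens of the spatial operators are patch vectors of length ``C·p²``
(all pixels of a ``p×p`` patch across channels); the frame operator's
tokens are whole flattened frames.  Q, K and V are produced by learnable
3×3 convolutions rather than linear layers, which keeps a locality bias
and lets the operators run on any matrix size.

Every public operator accepts either raw ndarrays or :class:`ImageSeries5D`
and returns an ndarray of the same 5D shape.  The same code paths, driven
through :mod:`cinedenoise.autodiff` tensors, power the trainable backbone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Module, Parameter, Tensor

__all__ = [
    "ConfigurationError",
    "GeometryError",
    "ImageSeries5D",
    "AttentionGeometry",
    "RelPosBias",
    "QKVProjection",
    "LogitCounter",
    "LOGIT_COUNTER",
    "attention_logit_count",
    "project_qkv",
    "partition_windows",
    "inverse_partition",
    "scaled_dot_attention",
    "local_attention",
    "global_attention",
    "frame_attention",
    "full_spatial_attention_oracle",
    "split_heads",
    "merge_heads",
]


class ConfigurationError(ValueError):
    """Invalid module configuration (channel/head/kernel mismatch)."""


class GeometryError(ValueError):
    """Window/patch geometry incompatible with the image size."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ImageSeries5D:
    """A complex or real image series indexed ``[B, C, F, H, W]``.

    The universal interchange type: B batch, C channels, F frames (time,
    depth or slice), H×W pixels.  Complex data is split into paired
    real/imag channels before entering the network.
    """

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 5:
            raise ValueError(
                f"ImageSeries5D requires exactly 5 axes, got {self.values.ndim}"
            )
        if min(self.values.shape) < 1:
            raise ValueError(f"all axes must be >= 1, got shape {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ImageSeries5D requires finite values")

    @property
    def is_complex(self) -> bool:
        return np.iscomplexobj(self.values)

    @property
    def shape(self):
        return self.values.shape

    def as_real_channels(self) -> "ImageSeries5D":
        """Complex C channels -> 2C real channels, paired (re_0, im_0, ...)."""
        if not self.is_complex:
            return self
        b, c, f, h, w = self.values.shape
        out = np.empty((b, 2 * c, f, h, w), dtype=self.values.real.dtype)
        out[:, 0::2] = self.values.real
        out[:, 1::2] = self.values.imag
        return ImageSeries5D(out)

    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass(frozen=True)
class AttentionGeometry:
    """Window size ``w``, patch size ``p`` (both square, pixels) and head count.

    ``P = (w/p)²`` patches per window; ``N = ceil(H/w)·ceil(W/w)`` windows
    per frame after padding.
    """

    window_px: int = 16
    patch_px: int = 4
    heads: int = 1

    def __post_init__(self):
        if self.window_px < 1 or self.patch_px < 1 or self.heads < 1:
            raise GeometryError("window, patch and head count must be >= 1")
        if self.window_px % self.patch_px != 0:
            raise GeometryError(
                f"window ({self.window_px}px) must be a multiple of "
                f"patch ({self.patch_px}px)"
            )

    @property
    def patches_per_side(self) -> int:
        return self.window_px // self.patch_px

    @property
    def patches_per_window(self) -> int:
        return self.patches_per_side**2

    def windows_per_frame(self, h: int, w: int) -> int:
        return math.ceil(h / self.window_px) * math.ceil(w / self.window_px)

    def token_length(self, channels: int) -> int:
        d = channels * self.patch_px**2
        if d % self.heads != 0:
            raise ConfigurationError(
                f"token length C*p^2 = {d} not divisible by {self.heads} heads"
            )
        return d


class RelPosBias(Module):
    """Learnable relative positional bias for within-window (local) attention.

    One scalar per head per relative patch offset ``(Δrow, Δcol)`` with
    ``Δ ∈ [-(w/p-1), w/p-1]``; materialized as an ``[h, P, P]`` matrix added
    to the attention logits before the row softmax.  Zero-initialized.
    """

    def __init__(self, geom: AttentionGeometry):
        super().__init__()
        q = geom.patches_per_side
        n_off = (2 * q - 1) ** 2
        self.table = Parameter(np.zeros((geom.heads, n_off), dtype=np.float32))
        rr, cc = np.meshgrid(np.arange(q), np.arange(q), indexing="ij")
        pos = np.stack([rr.ravel(), cc.ravel()], axis=1)  # [P, 2]
        dr = pos[:, None, 0] - pos[None, :, 0] + (q - 1)
        dc = pos[:, None, 1] - pos[None, :, 1] + (q - 1)
        self.index = dr * (2 * q - 1) + dc  # [P, P]

    def matrix(self) -> Tensor:
        return ad.gather_rows(self.table, self.index)  # [h, P, P]


class QKVProjection(Module):
    """Three independent learnable C→C convolutions (3×3, padding 1) that
    produce the query, key and value tensors, applied per frame with weights
    shared across frames.

    The key convolution carries no bias: a constant added to every key
    shifts each logit row uniformly, which the row softmax cancels, so a
    key bias would be an exactly gradient-free parameter.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.channels = channels
        scale = 1.0 / math.sqrt(channels * 9)
        shape = (channels, channels, 3, 3)
        self.wq = Parameter(rng.normal(0, scale, shape).astype(dtype))
        self.wk = Parameter(rng.normal(0, scale, shape).astype(dtype))
        self.wv = Parameter(rng.normal(0, scale, shape).astype(dtype))
        self.bq = Parameter(np.zeros(channels, dtype=dtype))
        self.bv = Parameter(np.zeros(channels, dtype=dtype))

    def forward(self, x: Tensor):
        b, c, f, h, w = x.shape
        if c != self.channels:
            raise ConfigurationError(
                f"input has {c} channels, projection expects {self.channels}"
            )
        flat = x.transpose(0, 2, 1, 3, 4).reshape(b * f, c, h, w)

        def back(t):
            return t.reshape(b, f, c, h, w).transpose(0, 2, 1, 3, 4)

        q = back(ad.conv2d(flat, self.wq, self.bq))
        k = back(ad.conv2d(flat, self.wk, None))
        v = back(ad.conv2d(flat, self.wv, self.bv))
        return q, k, v


# ---------------------------------------------------------------------------
# logit accounting
# ---------------------------------------------------------------------------


class LogitCounter:
    """Counts attention logits (entries of every coefficient matrix) computed
    by the operators; used to verify linear scaling in image size."""

    def __init__(self):
        self.enabled = False
        self.count = 0

    def reset(self):
        self.count = 0

    def add(self, n: int):
        if self.enabled:
            self.count += int(n)

    def __enter__(self):
        self.enabled = True
        self.reset()
        return self

    def __exit__(self, *exc):
        self.enabled = False
        return False


LOGIT_COUNTER = LogitCounter()


def attention_logit_count(geom: AttentionGeometry, h: int, w: int) -> dict:
    """Closed-form logit counts per frame per head: ``N·P²`` for local and
    ``P·N²`` for global attention — both linear in H·W at fixed (w, p)."""
    n = geom.windows_per_frame(h, w)
    p = geom.patches_per_window
    return {"local": n * p * p, "global": p * n * n}


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _vals(x) -> np.ndarray:
    if isinstance(x, ImageSeries5D):
        return x.values
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(_vals(x))


def _reflect_index(target: int, n: int) -> np.ndarray:
    """Reflection (mirror without edge repeat) of 0..target-1 onto 0..n-1."""
    if n == 1:
        return np.zeros(target, dtype=np.intp)
    period = 2 * n - 2
    j = np.arange(target, dtype=np.intp) % period
    return np.where(j < n, j, period - j)


@dataclass(frozen=True)
class PartitionInfo:
    """Bookkeeping needed to invert :func:`partition_windows`."""

    batch: int
    channels: int
    frames: int
    height: int
    width: int
    padded_h: int
    padded_w: int
    geom: AttentionGeometry = field(compare=False)

    @property
    def n_windows(self) -> int:
        w = self.geom.window_px
        return (self.padded_h // w) * (self.padded_w // w)


def _partition_t(x: Tensor, geom: AttentionGeometry):
    """Tensor-path window partition: [B,C,F,H,W] -> ([B,F,N,P,C·p²], info).

    H and W are reflect-padded up to multiples of the window size first.
    Token layout within a patch is channel-major (C, p, p) flattened.
    """
    b, c, f, h, w = x.shape
    win, p = geom.window_px, geom.patch_px
    hp = math.ceil(h / win) * win
    wp = math.ceil(w / win) * win
    if hp != h or wp != w:
        x = ad.index_hw(x, _reflect_index(hp, h), _reflect_index(wp, w))
    nh, nw = hp // win, wp // win
    q = geom.patches_per_side
    # [B,C,F,nH,q,p,nW,q,p] -> [B,F,nH,nW,q,q,C,p,p] -> [B,F,N,P,C*p*p]
    x = x.reshape(b, c, f, nh, q, p, nw, q, p)
    x = x.transpose(0, 2, 3, 6, 4, 7, 1, 5, 8)
    x = x.reshape(b, f, nh * nw, q * q, c * p * p)
    info = PartitionInfo(b, c, f, h, w, hp, wp, geom)
    return x, info


def _inverse_partition_t(win: Tensor, info: PartitionInfo) -> Tensor:
    g = info.geom
    q, p = g.patches_per_side, g.patch_px
    nh = info.padded_h // g.window_px
    nw = info.padded_w // g.window_px
    b, c, f = info.batch, info.channels, info.frames
    x = win.reshape(b, f, nh, nw, q, q, c, p, p)
    x = x.transpose(0, 6, 1, 2, 4, 7, 3, 5, 8)
    x = x.reshape(b, c, f, info.padded_h, info.padded_w)
    if info.padded_h != info.height or info.padded_w != info.width:
        x = ad.index_hw(x, np.arange(info.height), np.arange(info.width))
    return x


def partition_windows(x, geom: AttentionGeometry):
    """Partition a series into window/patch tokens.

    Returns ``(tokens, info)`` with ``tokens`` shaped ``[B, F, N, P, C·p²]``;
    invert with :func:`inverse_partition`.  Reflect-pads non-divisible H, W.
    """
    xv = _vals(x)
    if xv.ndim != 5:
        raise ValueError("expected a 5D [B,C,F,H,W] array")
    t, info = _partition_t(Tensor(xv), geom)
    return t.data, info


def inverse_partition(tokens, info: PartitionInfo) -> np.ndarray:
    """Exact inverse of :func:`partition_windows` on the unpadded region."""
    return _inverse_partition_t(_as_tensor(tokens), info).data


def split_heads(d: np.ndarray, heads: int):
    """Split the last axis of a ``[T, d]`` data matrix into ``h`` contiguous
    column groups (channel-major token layout makes these channel groups)."""
    d = np.asarray(d)
    if d.shape[-1] % heads != 0:
        raise ConfigurationError(
            f"token length {d.shape[-1]} not divisible by {heads} heads"
        )
    return [h for h in np.split(d, heads, axis=-1)]


def merge_heads(parts) -> np.ndarray:
    return np.concatenate(list(parts), axis=-1)


# ---------------------------------------------------------------------------
# attention primitives
# ---------------------------------------------------------------------------


def _attend(q: Tensor, k: Tensor, v: Tensor, bias: Tensor | None,
            scale_exponent: float):
    """Scaled-dot attention over the last two axes ``[..., T, d]``.

    Returns ``(output, weights)``; weights rows sum to one.  The logit scale
    is ``d**-scale_exponent`` with d the per-head token length.
    """
    d = q.shape[-1]
    scale = float(d) ** (-scale_exponent)
    logits = ad.matmul(q, k.transpose(*range(q.ndim - 2), q.ndim - 1, q.ndim - 2))
    logits = logits * scale
    if bias is not None:
        logits = logits + bias
    LOGIT_COUNTER.add(int(np.prod(logits.shape)))
    a = ad.softmax(logits, axis=-1)
    return ad.matmul(a, v), a


def scaled_dot_attention(dq, dk, dv, bias=None, scale_exponent: float = 0.5,
                         return_weights: bool = False):
    """Plain scaled dot-product attention on ``[T, d]`` data matrices.

    ``A = softmax(Dq·Dkᵀ / d^exponent + bias)`` row-wise; output ``A·Dv``.
    """
    dq, dk, dv = (np.asarray(m, dtype=float) for m in (dq, dk, dv))
    if not (dq.shape[-1] == dk.shape[-1] and dk.shape[0] == dv.shape[0]):
        raise ValueError("Dq/Dk/Dv dimensions do not match")
    bt = None if bias is None else Tensor(np.asarray(bias, dtype=float))
    out, a = _attend(Tensor(dq), Tensor(dk), Tensor(dv), bt, scale_exponent)
    return (out.data, a.data) if return_weights else out.data


def _local_attention_t(q: Tensor, k: Tensor, v: Tensor,
                       geom: AttentionGeometry, bias: RelPosBias | None,
                       scale_exponent: float = 0.5):
    """Tensor path of local attention; returns (output, weights)."""
    b, c, f, h, w = q.shape
    dh = geom.token_length(c) // geom.heads
    hh = geom.heads

    def tok(x):
        t, info = _partition_t(x, geom)
        bb, ff, n, p, _ = t.shape
        # heads are contiguous channel groups of the (C, p, p) layout
        t = t.reshape(bb, ff, n, p, hh, dh).transpose(0, 1, 2, 4, 3, 5)
        return t, info

    qt, info = tok(q)
    kt, _ = tok(k)
    vt, _ = tok(v)
    bmat = None if bias is None else bias.matrix()  # [h, P, P] broadcasts
    out, a = _attend(qt, kt, vt, bmat, scale_exponent)
    bb, ff, n, _, p, _ = out.shape
    out = out.transpose(0, 1, 2, 4, 3, 5).reshape(bb, ff, n, p, hh * dh)
    return _inverse_partition_t(out, info), a


def _global_attention_t(q: Tensor, k: Tensor, v: Tensor,
                        geom: AttentionGeometry, scale_exponent: float = 0.5):
    """Tensor path of global attention: tokens are same-position patches
    across windows; no positional bias (token count varies with size)."""
    b, c, f, h, w = q.shape
    dh = geom.token_length(c) // geom.heads
    hh = geom.heads

    def tok(x):
        t, info = _partition_t(x, geom)
        bb, ff, n, p, _ = t.shape
        t = t.reshape(bb, ff, n, p, hh, dh).transpose(0, 1, 3, 4, 2, 5)
        return t, info  # [B, F, P, h, N, dh]

    qt, info = tok(q)
    kt, _ = tok(k)
    vt, _ = tok(v)
    out, a = _attend(qt, kt, vt, None, scale_exponent)
    bb, ff, p, _, n, _ = out.shape
    out = out.transpose(0, 1, 4, 2, 3, 5).reshape(bb, ff, n, p, hh * dh)
    return _inverse_partition_t(out, info), a


def _frame_attention_t(q: Tensor, k: Tensor, v: Tensor, heads: int = 1,
                       scale_exponent: float = 0.5):
    """Tensor path of frame attention: each token is a whole flattened frame
    (length C·H·W), attention over the F axis; heads split the channel axis."""
    b, c, f, h, w = q.shape
    if c % heads != 0:
        raise ConfigurationError(f"{c} channels not divisible by {heads} heads")
    ch = c // heads

    def tok(x):
        return (
            x.reshape(b, heads, ch, f, h, w)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(b, heads, f, ch * h * w)
        )

    out, a = _attend(tok(q), tok(k), tok(v), None, scale_exponent)
    out = (
        out.reshape(b, heads, f, ch, h, w)
        .transpose(0, 1, 3, 2, 4, 5)
        .reshape(b, c, f, h, w)
    )
    return out, a


def project_qkv(x, proj: QKVProjection):
    """Compute Q, K, V via the three per-frame 3×3 convolutions."""
    q, k, v = proj(_as_tensor(_vals(x)))
    return q.data, k.data, v.data


def local_attention(q, k, v, geom: AttentionGeometry,
                    bias: RelPosBias | None = None,
                    scale_exponent: float = 0.5,
                    return_weights: bool = False):
    """Within-window patch attention, independently per (batch, frame,
    window, head); output reassembled to ``[B, C, F, H, W]``."""
    out, a = _local_attention_t(
        _as_tensor(q), _as_tensor(k), _as_tensor(v), geom, bias, scale_exponent
    )
    return (out.data, a.data) if return_weights else out.data


def global_attention(q, k, v, geom: AttentionGeometry,
                     scale_exponent: float = 0.5,
                     return_weights: bool = False):
    """Across-window attention among same-position patches per frame."""
    out, a = _global_attention_t(
        _as_tensor(q), _as_tensor(k), _as_tensor(v), geom, scale_exponent
    )
    return (out.data, a.data) if return_weights else out.data


def frame_attention(q, k, v, heads: int = 1, scale_exponent: float = 0.5,
                    return_weights: bool = False):
    """Full attention along the frame axis; tokens are whole frames."""
    out, a = _frame_attention_t(
        _as_tensor(q), _as_tensor(k), _as_tensor(v), heads, scale_exponent
    )
    return (out.data, a.data) if return_weights else out.data


def full_spatial_attention_oracle(q, k, v, scale_exponent: float = 0.5):
    """Exhaustive pixel-token spatial attention, written with explicit loops.

    Reference implementation for small instances (H·W ≤ ~1024): every pixel
    is a token with its C-channel vector; no windowing.  Local attention
    with w = H = W, p = 1 and global attention with w = p = 1 must both
    reduce to this.
    """
    qv, kv, vv = (np.asarray(_vals(m), dtype=float) for m in (q, k, v))
    b, c, f, h, w = qv.shape
    t = h * w
    scale = float(c) ** (-scale_exponent)
    out = np.empty_like(qv)
    for bi in range(b):
        for fi in range(f):
            dq = qv[bi, :, fi].reshape(c, t).T
            dk = kv[bi, :, fi].reshape(c, t).T
            dv = vv[bi, :, fi].reshape(c, t).T
            res = np.empty((t, c))
            for ti in range(t):
                logits = np.empty(t)
                for tj in range(t):
                    logits[tj] = np.dot(dq[ti], dk[tj]) * scale
                ex = np.exp(logits - logits.max())
                a_row = ex / ex.sum()
                res[ti] = a_row @ dv
            out[bi, :, fi] = res.T.reshape(c, h, w)
    return out
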
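"""Independently coded brute-force reference implementations.

Testing namespace: slow, loop-explicit oracles kept deliberately separate
from (and structurally unlike) the vectorized operators they check.  Use
on small instances only.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "scaled_dot_bruteforce",
    "frame_attention_bruteforce",
    "conv2d_bruteforce",
    "full_spatial_attention",
]


def scaled_dot_bruteforce(dq, dk, dv, bias=None, scale_exponent=0.5):
    """Two-loop softmax attention on [T, d] matrices."""
    dq, dk, dv = (np.asarray(m, dtype=float) for m in (dq, dk, dv))
    t, d = dq.shape
    scale = d ** (-scale_exponent)
    out = np.zeros((t, dv.shape[1]))
    for i in range(t):
        logits = np.zeros(t)
        for j in range(t):
            acc = 0.0
            for m in range(d):
                acc += dq[i, m] * dk[j, m]
            logits[j] = acc * scale
            if bias is not None:
                logits[j] += bias[i, j]
        logits -= logits.max()
        weights = np.exp(logits)
        weights /= weights.sum()
        for j in range(t):
            out[i] += weights[j] * dv[j]
    return out


def frame_attention_bruteforce(q, k, v, heads: int = 1,
                               scale_exponent: float = 0.5):
    """Whole-frame token attention along F, one head group at a time."""
    q, k, v = (np.asarray(m, dtype=float) for m in (q, k, v))
    b, c, f, h, w = q.shape
    ch = c // heads
    out = np.zeros_like(q)
    for bi in range(b):
        for hd in range(heads):
            sl = slice(hd * ch, (hd + 1) * ch)
            dq = q[bi, sl].transpose(1, 0, 2, 3).reshape(f, -1)
            dk = k[bi, sl].transpose(1, 0, 2, 3).reshape(f, -1)
            dv = v[bi, sl].transpose(1, 0, 2, 3).reshape(f, -1)
            res = scaled_dot_bruteforce(dq, dk, dv,
                                        scale_exponent=scale_exponent)
            out[bi, sl] = res.reshape(f, ch, h, w).transpose(1, 0, 2, 3)
    return out


def conv2d_bruteforce(x, w, b=None, stride=1, padding=1):
    """Direct quadruple-loop 2D cross-correlation, [N,C,H,W] x [Co,C,kh,kw]."""
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    n, c, h, wd = x.shape
    co, _, kh, kw = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (wd + 2 * padding - kw) // stride + 1
    out = np.zeros((n, co, ho, wo))
    for ni in range(n):
        for oi in range(co):
            for yi in range(ho):
                for xi in range(wo):
                    acc = 0.0
                    for ci in range(c):
                        for i in range(kh):
                            for j in range(kw):
                                acc += (w[oi, ci, i, j]
                                        * xp[ni, ci, yi * stride + i,
                                             xi * stride + j])
                    out[ni, oi, yi, xi] = acc
            if b is not None:
                out[ni, oi] += b[oi]
    return out


def full_spatial_attention(q, k, v, scale_exponent: float = 0.5):
    """Alias of the exhaustive pixel-token oracle (lives with the operators
    so both decomposed paths can cross-check against one function)."""
    from .attention import full_spatial_attention_oracle

    return full_spatial_attention_oracle(q, k, v, scale_exponent)
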
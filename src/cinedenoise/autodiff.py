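"""Minimal reverse-mode automatic differentiation over numpy arrays.

This is the compute core under the attention operators and the denoising
backbone: a tape-based scalar-loss autodiff engine providing exactly the
operations the model needs (batched matmul, 2D convolution via im2col,
layer normalization, softmax, PReLU, dropout, index gather for padding and
positional-bias lookup, nearest-neighbour upsampling) plus a ``Module``
parameter container and an Adam optimizer.

Every primitive registers a closed-form backward; correctness is enforced
by finite-difference gradient checks in the test suite.  The engine is
deliberately small and eager — no graph optimization, no fused kernels.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "ModuleList",
    "Adam",
    "matmul",
    "softmax",
    "layer_norm",
    "conv2d",
    "prelu",
    "dropout",
    "index_hw",
    "gather_rows",
    "upsample2x_nearest",
    "mse_loss",
    "numeric_gradient",
]


def _as_array(x):
    return x.data if isinstance(x, Tensor) else np.asarray(x)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, (g_dim, s_dim) in enumerate(zip(grad.shape, shape)):
        if s_dim == 1 and g_dim != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus the local backward rules that produced it.

    ``_parents`` is a tuple of ``(tensor, grad_fn)`` pairs; ``grad_fn`` maps
    the upstream gradient to this parent's gradient contribution.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in _parents
        )
        self.grad = None
        self._parents = _parents if self.requires_grad else ()

    # -- graph traversal ---------------------------------------------------

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for parent, _ in node._parents:
                visit(parent)
            topo.append(node)

        visit(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node.grad is None:
                continue
            for parent, grad_fn in node._parents:
                if not parent.requires_grad:
                    continue
                contrib = grad_fn(node.grad)
                if parent.grad is None:
                    if contrib.dtype != parent.data.dtype:
                        contrib = contrib.astype(parent.data.dtype)
                    elif contrib is node.grad or contrib.base is not None:
                        # views of upstream grads must not be shared in place
                        contrib = contrib.copy()
                    parent.grad = contrib
                else:
                    parent.grad += contrib

    # -- convenience -------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic --------------------------------------------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data
        return Tensor(
            out_data,
            _parents=(
                (self, lambda g: _unbroadcast(g, self.data.shape)),
                (other, lambda g: _unbroadcast(g, other.data.shape)),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor(-self.data, _parents=((self, lambda g: -g),))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return Tensor(
            self.data * other.data,
            _parents=(
                (self, lambda g: _unbroadcast(g * other.data, self.data.shape)),
                (other, lambda g: _unbroadcast(g * self.data, other.data.shape)),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return Tensor(
            self.data / other.data,
            _parents=(
                (self, lambda g: _unbroadcast(g / other.data, self.data.shape)),
                (
                    other,
                    lambda g: _unbroadcast(
                        -g * self.data / other.data**2, other.data.shape
                    ),
                ),
            ),
        )

    def __pow__(self, exponent: float):
        out = self.data**exponent
        return Tensor(
            out,
            _parents=(
                (self, lambda g: g * exponent * self.data ** (exponent - 1)),
            ),
        )

    def __matmul__(self, other):
        return matmul(self, other)

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor(
            self.data.reshape(shape),
            _parents=((self, lambda g: g.reshape(old)),),
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor(
            self.data.transpose(axes),
            _parents=((self, lambda g: g.transpose(inv)),),
        )

    def __getitem__(self, key):
        out = self.data[key]

        def grad_fn(g, key=key):
            full = np.zeros_like(self.data)
            full[key] = g
            return full

        return Tensor(out, _parents=((self, grad_fn),))

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def grad_fn(g):
            if axis is None:
                return np.broadcast_to(g, self.data.shape).copy()
            gg = g if keepdims else np.expand_dims(g, axis)
            return np.broadcast_to(gg, self.data.shape).copy()

        return Tensor(out, _parents=((self, grad_fn),))

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / float(n)


class Parameter(Tensor):
    """A leaf tensor updated by the optimizer."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)


# ---------------------------------------------------------------------------
# functional primitives
# ---------------------------------------------------------------------------


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """Batched matrix product with numpy broadcasting on leading axes."""
    a = a if isinstance(a, Tensor) else Tensor(a)
    b = b if isinstance(b, Tensor) else Tensor(b)
    out = a.data @ b.data

    def grad_a(g):
        return _unbroadcast(g @ np.swapaxes(b.data, -1, -2), a.data.shape)

    def grad_b(g):
        return _unbroadcast(np.swapaxes(a.data, -1, -2) @ g, b.data.shape)

    return Tensor(out, _parents=((a, grad_a), (b, grad_b)))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    xd = x.data
    if not np.all(np.isfinite(xd)):
        raise FloatingPointError(
            "non-finite attention logits "
            f"(min={np.nanmin(xd)!r}, max={np.nanmax(xd)!r})"
        )
    m = xd.max(axis=axis, keepdims=True)
    e = np.exp(xd - m)
    s = e / e.sum(axis=axis, keepdims=True)

    def grad_fn(g):
        return s * (g - (g * s).sum(axis=axis, keepdims=True))

    return Tensor(s, _parents=((x, grad_fn),))


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, axis: int = 1,
               eps: float = 1e-5) -> Tensor:
    """Normalize over one axis (mean 0, var 1), then scale/shift.

    ``gamma``/``beta`` must broadcast against ``x`` (e.g. shape
    ``[1, C, 1, 1, 1]`` for channel normalization of a 5D series).
    """
    xd = x.data
    mu = xd.mean(axis=axis, keepdims=True)
    var = xd.var(axis=axis, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * inv
    out = xhat * gamma.data + beta.data
    n = xd.shape[axis]

    def grad_x(g):
        dxhat = g * gamma.data
        t1 = dxhat.mean(axis=axis, keepdims=True)
        t2 = (dxhat * xhat).mean(axis=axis, keepdims=True)
        return inv * (dxhat - t1 - xhat * t2)

    def grad_gamma(g):
        return _unbroadcast(g * xhat, gamma.data.shape)

    def grad_beta(g):
        return _unbroadcast(g, beta.data.shape)

    return Tensor(
        out, _parents=((x, grad_x), (gamma, grad_gamma), (beta, grad_beta))
    )


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 1) -> Tensor:
    """2D convolution (cross-correlation) via im2col, zero padding.

    ``x``: [N, Cin, H, W]; ``w``: [Cout, Cin, kh, kw]; ``b``: [Cout].
    """
    xd, wd = x.data, w.data
    n_img, c_in, h_in, w_in = xd.shape
    c_out, c_in_w, kh, kw = wd.shape
    if c_in != c_in_w:
        raise ValueError(
            f"channel mismatch: input has {c_in} channels, kernel expects {c_in_w}"
        )
    xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    h_out = (h_in + 2 * padding - kh) // stride + 1
    w_out = (w_in + 2 * padding - kw) // stride + 1
    # column layout [N, C*kh*kw, Ho*Wo] built from contiguous slab copies;
    # keeps the heavy work inside batched BLAS matmuls.
    cols = np.empty((n_img, c_in, kh, kw, h_out, w_out), dtype=xd.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[:, :, i : i + stride * h_out : stride,
                                  j : j + stride * w_out : stride]
    cols3 = cols.reshape(n_img, c_in * kh * kw, h_out * w_out)
    w2 = wd.reshape(c_out, -1)
    out3 = w2 @ cols3  # [N, Cout, Ho*Wo]
    out = out3.reshape(n_img, c_out, h_out, w_out)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def grad_x(g):
        g3 = g.reshape(n_img, c_out, h_out * w_out)
        dcols = (w2.T @ g3).reshape(n_img, c_in, kh, kw, h_out, w_out)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + stride * h_out : stride,
                    j : j + stride * w_out : stride] += dcols[:, :, i, j]
        return dxp[:, :, padding : padding + h_in, padding : padding + w_in]

    def grad_w(g):
        g3 = g.reshape(n_img, c_out, h_out * w_out)
        dw = np.matmul(g3, cols3.transpose(0, 2, 1)).sum(axis=0)
        return dw.reshape(wd.shape)

    parents = [(x, grad_x), (w, grad_w)]
    if b is not None:
        parents.append((b, lambda g: g.sum(axis=(0, 2, 3))))
    return Tensor(out, _parents=tuple(parents))


def prelu(x: Tensor, a: Tensor) -> Tensor:
    """PReLU with a single learnable slope for the negative part."""
    xd = x.data
    pos = xd > 0
    out = np.where(pos, xd, a.data * xd)

    def grad_x(g):
        return np.where(pos, g, a.data * g)

    def grad_a(g):
        return np.asarray((g * xd * (~pos)).sum()).reshape(a.data.shape)

    return Tensor(out, _parents=((x, grad_x), (a, grad_a)))


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return x
    keep = 1.0 - rate
    mask = (rng.random(x.data.shape) < keep).astype(x.data.dtype) / keep
    return Tensor(x.data * mask, _parents=((x, lambda g: g * mask),))


def index_hw(x: Tensor, rows: np.ndarray, cols: np.ndarray) -> Tensor:
    """Gather along the last two axes: ``out[..., i, j] = x[..., rows[i], cols[j]]``.

    With reflected indices this implements reflect-padding; with a slice of
    ``arange`` it implements cropping.  Backward scatter-adds, so duplicated
    source pixels accumulate gradient correctly.
    """
    rows = np.asarray(rows, dtype=np.intp)
    cols = np.asarray(cols, dtype=np.intp)
    out = x.data[..., rows[:, None], cols[None, :]]

    def grad_fn(g):
        dx = np.zeros_like(x.data)
        np.add.at(dx, (Ellipsis, rows[:, None], cols[None, :]), g)
        return dx

    return Tensor(out, _parents=((x, grad_fn),))


def gather_rows(table: Tensor, idx: np.ndarray) -> Tensor:
    """Embedding-style lookup ``out[..., i, j] = table[..., idx[i, j]]``.

    Used for the relative-positional-bias table: ``table`` is
    ``[heads, n_offsets]`` and ``idx`` is the ``[P, P]`` offset-index matrix.
    """
    idx = np.asarray(idx, dtype=np.intp)
    out = table.data[..., idx]

    def grad_fn(g):
        dt = np.zeros_like(table.data)
        np.add.at(dt.reshape(-1, dt.shape[-1]),
                  (slice(None), idx.ravel()),
                  g.reshape(dt.shape[0] if dt.ndim > 1 else 1, -1))
        return dt

    return Tensor(out, _parents=((table, grad_fn),))


def upsample2x_nearest(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of the last two axes."""
    out = x.data.repeat(2, axis=-2).repeat(2, axis=-1)

    def grad_fn(g):
        s = g.shape
        return g.reshape(*s[:-2], s[-2] // 2, 2, s[-1] // 2, 2).sum(axis=(-3, -1))

    return Tensor(out, _parents=((x, grad_fn),))


def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred - Tensor(np.asarray(target, dtype=pred.data.dtype))
    return (diff * diff).mean()


# ---------------------------------------------------------------------------
# modules and optimizer
# ---------------------------------------------------------------------------


class Module:
    """Parameter container with recursive traversal and train/eval mode."""

    def __init__(self):
        self.training = True

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for value in vars(self).values():
            if isinstance(value, Module):
                value.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._items = list(modules)
        for i, m in enumerate(self._items):
            setattr(self, f"m{i}", m)

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


class Adam:
    """Adam with decoupled hyperparameters; ``lr`` may change per step."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self, lr: float | None = None):
        if lr is not None:
            self.lr = lr
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def numeric_gradient(f, x: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of scalar ``f`` at ``x`` (float64)."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    flat = x.ravel()
    gflat = g.ravel()
    for i in range(flat.size):
        orig = flat[i]
        flat[i] = orig + eps
        fp = f(x)
        flat[i] = orig - eps
        fm = f(x)
        flat[i] = orig
        gflat[i] = (fp - fm) / (2 * eps)
    return g
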
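"""Reverse-mode automatic differentiation over NumPy arrays.

This is the computational core the detector is built on: a small, explicit
tape of :class:`Tensor` nodes whose backward closures implement the vector–
Jacobian products of the handful of primitives a convolutional detector
needs (convolution, batch normalization, pooling, matrix products, the
usual pointwise maps, and a numerically stable softmax / binary
cross-entropy).  Everything is float32; gradients accumulate into
``Tensor.grad``.

The design goal is correctness and transparency, not generality: only the
operations used by the model and its losses exist, and each backward rule
is the textbook formula written against NumPy broadcasting.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "as_tensor", "concat", "stack", "conv2d", "batch_norm",
    "max_pool2d", "upsample_nearest2x", "softmax", "sigmoid", "silu",
    "relu", "bce_with_logits",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # release closure + graph edges once consumed
                node._backward = None
                node._parents = ()

    def _accum(self, g: np.ndarray):
        if not self.requires_grad:
            return
        g = g.astype(np.float32, copy=False)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            a._accum(_unbroadcast(g, a.data.shape))
            b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: a._accum(-g))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            a._accum(_unbroadcast(g * b.data, a.data.shape))
            b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other
        out = a.data / b.data

        def bw(g):
            a._accum(_unbroadcast(g / b.data, a.data.shape))
            b._accum(_unbroadcast(-g * out / b.data, b.data.shape))

        return Tensor._make(out, (a, b), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        a = self
        out = a.data ** p
        return Tensor._make(out, (a,), lambda g: a._accum(g * p * a.data ** (p - 1)))

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        out = a.data @ b.data

        def bw(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            a._accum(_unbroadcast(ga, a.data.shape))
            b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._make(out, (a, b), bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accum(np.broadcast_to(g, a.data.shape))

        return Tensor._make(out, (a,), bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims=False):
        a = self
        out = a.data.max(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            o = out
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
                o = np.expand_dims(o, axis)
            mask = (a.data == o).astype(np.float32)
            mask /= np.maximum(mask.sum(axis=axis, keepdims=True), 1.0) if axis is not None else max(mask.sum(), 1.0)
            a._accum(mask * g)

        return Tensor._make(out, (a,), bw)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.data.shape
        return Tensor._make(a.data.reshape(shape), (a,),
                            lambda g: a._accum(g.reshape(old)))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)
        return Tensor._make(a.data.transpose(axes), (a,),
                            lambda g: a._accum(g.transpose(inv)))

    @property
    def T(self):
        return self.transpose(*reversed(range(self.ndim)))

    def __getitem__(self, idx):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._make(a.data[idx], (a,), bw)

    # -- pointwise maps -------------------------------------------------------
    def exp(self):
        a = self
        out = np.exp(a.data)
        return Tensor._make(out, (a,), lambda g: a._accum(g * out))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: a._accum(g / a.data))

    def sqrt(self):
        a = self
        out = np.sqrt(a.data)
        return Tensor._make(out, (a,), lambda g: a._accum(g * 0.5 / out))

    def arctan(self):
        a = self
        return Tensor._make(np.arctan(a.data), (a,),
                            lambda g: a._accum(g / (1.0 + a.data * a.data)))

    def clip(self, lo, hi):
        a = self
        out = np.clip(a.data, lo, hi)
        mask = ((a.data >= lo) & (a.data <= hi)).astype(np.float32)
        return Tensor._make(out, (a,), lambda g: a._accum(g * mask))

    def maximum(self, other):
        other = as_tensor(other)
        a, b = self, other
        out = np.maximum(a.data, b.data)
        mask = (a.data >= b.data).astype(np.float32)

        def bw(g):
            a._accum(_unbroadcast(g * mask, a.data.shape))
            b._accum(_unbroadcast(g * (1.0 - mask), b.data.shape))

        return Tensor._make(out, (a, b), bw)

    def minimum(self, other):
        other = as_tensor(other)
        a, b = self, other
        out = np.minimum(a.data, b.data)
        mask = (a.data <= b.data).astype(np.float32)

        def bw(g):
            a._accum(_unbroadcast(g * mask, a.data.shape))
            b._accum(_unbroadcast(g * (1.0 - mask), b.data.shape))

        return Tensor._make(out, (a, b), bw)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    out = np.concatenate([t.data for t in tensors], axis=axis)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    return Tensor._make(out, tensors, bw)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            t._accum(np.take(g, i, axis=axis))

    return Tensor._make(out, tensors, bw)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = 0.5 * (1.0 + np.tanh(0.5 * x.data))
    return Tensor._make(out, (x,), lambda g: x._accum(g * out * (1.0 - out)))


def silu(x: Tensor) -> Tensor:
    """x * sigmoid(x) — the activation used throughout the detector."""
    x = as_tensor(x)
    s = 0.5 * (1.0 + np.tanh(0.5 * x.data))
    out = x.data * s
    return Tensor._make(out, (x,), lambda g: x._accum(g * (s * (1.0 + x.data * (1.0 - s)))))


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = (x.data > 0).astype(np.float32)
    return Tensor._make(x.data * mask, (x,), lambda g: x._accum(g * mask))


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Row-max-stabilized softmax (the stabilization is an identity)."""
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    out = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * out).sum(axis=axis, keepdims=True)
        x._accum(out * (g - dot))

    return Tensor._make(out, (x,), bw)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Element-wise binary cross-entropy on sigmoid(logits), numerically stable.

    ``targets`` are plain arrays (no gradient): soft labels in [0, 1].
    """
    x = as_tensor(logits)
    t = np.asarray(targets, dtype=np.float32)
    loss = np.maximum(x.data, 0) - x.data * t + np.log1p(np.exp(-np.abs(x.data)))
    s = 0.5 * (1.0 + np.tanh(0.5 * x.data))
    return Tensor._make(loss, (x,), lambda g: x._accum(g * (s - t)))


# ---------------------------------------------------------------------------
# structured primitives
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, via im2col + BLAS matmul."""
    x, w = as_tensor(x), as_tensor(w)
    n, c, h, wd = x.data.shape
    co, ci, kh, kw = w.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight expects {ci}")
    s, p = stride, padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    ho = (h + 2 * p - kh) // s + 1
    wo = (wd + 2 * p - kw) // s + 1
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))[:, :, ::s, ::s]
    # (n, c, ho, wo, kh, kw) -> (n*ho*wo, c*kh*kw)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * ho * wo, c * kh * kw)
    wm = w.data.reshape(co, -1)
    out = cols @ wm.T
    if b is not None:
        out = out + as_tensor(b).data
    y = out.reshape(n, ho, wo, co).transpose(0, 3, 1, 2)
    parents = (x, w) if b is None else (x, w, as_tensor(b))

    def bw(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, co)
        if w.requires_grad:
            w._accum((gm.T @ cols).reshape(w.data.shape))
        if b is not None and parents[2].requires_grad:
            parents[2]._accum(gm.sum(axis=0))
        if x.requires_grad:
            dcols = gm @ wm
            dwin = dcols.reshape(n, ho, wo, c, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dwin[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            x._accum(dxp[:, :, p:p + h, p:p + wd] if p else dxp)

    return Tensor._make(y, parents, bw)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.03, eps: float = 1e-3) -> Tensor:
    """Per-channel batch normalization (NCHW).  Updates running stats in place
    when ``training`` is true; uses them verbatim otherwise."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    axes = (0, 2, 3)
    shape = (1, -1, 1, 1)
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(shape)) * inv.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)

    def bw(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if x.requires_grad:
            gs = gamma.data.reshape(shape) * inv.reshape(shape)
            if training:
                m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                mean_g = g.mean(axis=axes, keepdims=True)
                mean_gx = (g * xhat).mean(axis=axes, keepdims=True)
                x._accum(gs * (g - mean_g - xhat * mean_gx))
                del m
            else:
                x._accum(gs * g)

    return Tensor._make(out, (x, gamma, beta), bw)


def max_pool2d(x: Tensor, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    s, p, k = stride, padding, kernel
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf) if p else x.data
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
    ho, wo = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, ho, wo, k * k)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bw(g):
        dxp = np.zeros_like(xp)
        ii, jj = np.divmod(arg, k)
        ns, cs, hs, ws = np.indices(arg.shape, sparse=False)
        np.add.at(dxp, (ns, cs, hs * s + ii, ws * s + jj), g)
        x._accum(dxp[:, :, p:p + h, p:p + w] if p else dxp)

    return Tensor._make(np.ascontiguousarray(out), (x,), bw)


def upsample_nearest2x(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)
    n, c, h, w = x.data.shape

    def bw(g):
        x._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

    return Tensor._make(out, (x,), bw)
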
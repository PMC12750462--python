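"""Minimal reverse-mode automatic differentiation over numpy arrays.

The trainable parts of the framework (lightweight CNN backbone, cross-attention
alignment, subspace heads, gating network) are small enough that a vectorized
numpy engine trains them in seconds on one CPU.  All arithmetic is float64 and
single-threaded numpy, so runs are bit-reproducible given the seeds.

Only the operations the models need are implemented.  Gradients accumulate in
``Tensor.grad``; call :meth:`Tensor.backward` on a scalar loss.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "softmax",
    "logsumexp",
    "softplus",
    "conv2d",
    "no_grad",
    "default_dtype",
]

_grad_enabled = True

#: engine-wide float dtype; float64 by default.  Federated training switches
#: to float32 (see ``default_dtype``) — on one CPU the GEMMs dominate and
#: float32 roughly halves their cost, while runs stay bit-reproducible.
DTYPE = np.float64


class default_dtype:
    """Context manager setting the engine dtype for tensors created inside."""

    def __init__(self, dtype):
        self.dtype = np.dtype(dtype).type

    def __enter__(self):
        global DTYPE
        self._prev = DTYPE
        DTYPE = self.dtype
        return self

    def __exit__(self, *exc):
        global DTYPE
        DTYPE = self._prev
        return False


class no_grad:
    """Context manager: ops inside build no graph (inference passes)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_bw", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._bw = None
        self._prev = _prev if _grad_enabled else ()

    # setting _backward is a no-op inside ``no_grad`` so backward closures
    # (which pin large intermediate buffers) are dropped immediately
    @property
    def _backward(self):
        return self._bw

    @_backward.setter
    def _backward(self, fn):
        self._bw = fn if _grad_enabled else None

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar")
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.ones_like(self.data))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
        # tear the graph down eagerly: intermediate buffers (im2col columns
        # especially) are large, and graphs are single-use here
        for t in topo:
            t._bw = None
            t._prev = ()
            if not t.requires_grad and t is not self:
                t.grad = None

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _prev=(self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return as_tensor(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1.0))
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            self._accum(g @ other.data.T)
            other._accum(self.data.T @ g)

        out._backward = bw
        return out

    # -- elementwise nonlinearities --------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _prev=(self,))
        out._backward = lambda g: self._accum(g * mask)
        return out

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, _prev=(self,))
        # capture the array, not `out`: a closure referencing its own tensor
        # creates a reference cycle that delays freeing large graphs
        out._backward = lambda g: self._accum(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, _prev=(self,))
        out._backward = lambda g: self._accum(g * s * (1.0 - s))
        return out

    # -- reductions / shape ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def bw(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in np.atleast_1d(axis)])
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    @property
    def T(self):
        out = Tensor(self.data.T, _prev=(self,))
        out._backward = lambda g: self._accum(g.T)
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def logsumexp(x: Tensor, axis: int = 1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)  # constant shift, no gradient
    z = x - Tensor(m)
    return z.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    return (x - logsumexp(x, axis=axis)).exp()


def softplus(x: Tensor) -> Tensor:
    """log(1 + e^x), numerically stable."""
    out = Tensor(np.logaddexp(0.0, x.data), _prev=(x,))
    sig = 1.0 / (1.0 + np.exp(-np.clip(x.data, -500, 500)))
    out._backward = lambda g: x._accum(g * sig)
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (NCHW) by im2col; backward scatters through col2im."""
    xd = x.data
    n, c, h, wd = xd.shape
    oc, ic, k, k2 = w.data.shape
    if ic != c or k != k2:
        raise ValueError("kernel/channel mismatch")
    xp = np.pad(xd, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else xd
    oh = (h + 2 * pad - k) // stride + 1
    ow = (wd + 2 * pad - k) // stride + 1
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    col = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * oh * ow, c * k * k)
    wmat = w.data.reshape(oc, -1)
    out_flat = col @ wmat.T
    y = out_flat.reshape(n, oh, ow, oc).transpose(0, 3, 1, 2)
    prev = (x, w) if b is None else (x, w, b)
    if b is not None:
        y = y + b.data.reshape(1, oc, 1, 1)
    out = Tensor(y, _prev=prev)

    def bw(g):
        gflat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * oh * ow, oc)
        w._accum((gflat.T @ col).reshape(w.data.shape))
        if b is not None:
            b._accum(gflat.sum(axis=0))
        dcol = (gflat @ wmat).reshape(n, oh, ow, c, k, k)
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + oh * stride:stride, j:j + ow * stride:stride] += (
                    dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
                )
        x._accum(dxp[:, :, pad:pad + h, pad:pad + wd] if pad else dxp)

    out._backward = bw
    return out
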
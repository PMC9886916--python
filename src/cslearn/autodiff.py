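"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ``numpy.ndarray`` together with a gradient
buffer and a closure that propagates upstream gradients to its inputs.
Calling :meth:`Tensor.backward` on a scalar runs the tape in reverse
topological order. The op set is deliberately small: exactly what the
embedding network, the GAN and the loss functions in this package need
(elementwise arithmetic, matmul, reductions, indexing, 2-D convolution and
transposed convolution via im2col/col2im).

Everything is double precision so analytic gradients can be checked against
central finite differences at tight tolerances.
"""

from __future__ import annotations

from contextlib import contextmanager
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "concatenate",
    "logsumexp",
    "conv2d",
    "conv_transpose2d",
]

# Global switch: inside `no_grad()` no tape is recorded.
_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    """Context manager that disables tape recording (evaluation mode)."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` by summing over broadcast axes."""
    if grad.shape == shape:
        return grad
    # Sum the leading axes numpy prepended during broadcasting.
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "_is_param")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev: tuple = ()
        self._is_param = False

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, prev: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED[-1] and any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = tuple(p for p in prev if p.requires_grad)
            out._backward = backward
        return out

    @staticmethod
    def as_tensor(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    # -- bookkeeping ----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs from deep nets overflow recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ----------------------------------------------
    def __add__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor.as_tensor(other))

    def __rsub__(self, other):
        return Tensor.as_tensor(other) + (-self)

    def __mul__(self, other):
        other = Tensor.as_tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor.as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor.as_tensor(other) * self**-1.0

    def __pow__(self, exponent: float):
        e = float(exponent)
        out_data = self.data**e

        def backward(g):
            self._accumulate(g * e * self.data ** (e - 1.0))

        return Tensor._make(out_data, (self,), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))

        def backward(g):
            self._accumulate(g * s * (1.0 - s))

        return Tensor._make(s, (self,), backward)

    def log_sigmoid(self):
        # Stable log σ(x) = -softplus(-x); gradient is 1 - σ(x).
        x = self.data
        out_data = np.where(x >= 0, -np.log1p(np.exp(-x)), x - np.log1p(np.exp(x)))
        s = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))

        def backward(g):
            self._accumulate(g * (1.0 - s))

        return Tensor._make(out_data, (self,), backward)

    def maximum(self, floor: float):
        """Elementwise max with a scalar; zero gradient where clamped."""
        mask = self.data > floor

        def backward(g):
            self._accumulate(g * mask)

        return Tensor._make(np.maximum(self.data, floor), (self,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)

        def backward(g):
            if axis is None:
                full = out_data
                gg = g
            else:
                full = self.data.max(axis=axis, keepdims=True)
                gg = g if keepdims else np.expand_dims(g, axis)
            mask = self.data == full
            counts = mask.sum(axis=axis, keepdims=True) if axis is not None else mask.sum()
            self._accumulate(gg * mask / counts)  # ties share the gradient

        return Tensor._make(out_data, (self,), backward)

    def min(self, axis=None, keepdims: bool = False):
        return -((-self).max(axis=axis, keepdims=keepdims))

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(orig))

        return Tensor._make(self.data.reshape(shape), (self,), backward)

    @property
    def T(self):
        def backward(g):
            self._accumulate(g.T)

        return Tensor._make(self.data.T, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            buf = np.zeros_like(self.data)
            np.add.at(buf, idx, g)
            self._accumulate(buf)

        return Tensor._make(out_data, (self,), backward)

    # -- linear algebra -------------------------------------------------------
    def matmul(self, other: "Tensor"):
        other = Tensor.as_tensor(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                grad_o = self.data.swapaxes(-1, -2) @ g
                other._accumulate(_unbroadcast(grad_o, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __matmul__ = matmul

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


# -- free functions -----------------------------------------------------------

def concatenate(tensors: Iterable[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor.as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])

    return Tensor._make(out_data, tensors, backward)


def logsumexp(t: Tensor, axis: int = -1, keepdims: bool = False) -> Tensor:
    """Numerically stable log-sum-exp along ``axis`` (max-subtraction trick)."""
    m = t.data.max(axis=axis, keepdims=True)  # constant shift, no gradient
    shifted = t - Tensor(m)
    out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    if not keepdims:
        shape = list(out.shape)
        shape.pop(axis)
        out = out.reshape(shape)
    return out


# -- 2-D convolution via im2col/col2im ----------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(N,C,H,W) -> (N, C*kh*kw, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return view.reshape(n, c * kh * kw, ho * wo), ho, wo


def _col2im(cols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    """Adjoint of :func:`_im2col`: scatter-add patches back to (N,C,H,W)."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    cols = cols.reshape(n, c, kh, kw, ho, wo)
    out = np.zeros((n, c, hp, wp), dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, i, j]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1, pad: int = 0) -> Tensor:
    """x: (N,Cin,H,W), w: (Cout,Cin,kh,kw), b: (Cout,) -> (N,Cout,Ho,Wo)."""
    n = x.data.shape[0]
    cout, cin, kh, kw = w.data.shape
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out_data = np.matmul(wmat, cols).reshape(n, cout, ho, wo)
    if b is not None:
        out_data += b.data.reshape(1, cout, 1, 1)
    prev = (x, w) if b is None else (x, w, b)

    def backward(g):
        gmat = g.reshape(n, cout, ho * wo)
        if w.requires_grad:
            gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.matmul(wmat.T, gmat)
            x._accumulate(_col2im(gcols, x.data.shape, kh, kw, stride, pad))

    return Tensor._make(out_data, prev, backward)


def conv_transpose2d(
    x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 2, pad: int = 1
) -> Tensor:
    """Transposed convolution. x: (N,Cin,H,W), w: (Cin,Cout,kh,kw).

    Output spatial size is ``stride*(H-1) + kh - 2*pad`` (the adjoint of a
    stride-``stride`` convolution with the same kernel/padding).
    """
    n, cin, hi, wi = x.data.shape
    cin_w, cout, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError("channel mismatch between input and weight")
    ho = stride * (hi - 1) + kh - 2 * pad
    wo = stride * (wi - 1) + kw - 2 * pad
    wmat = w.data.reshape(cin, cout * kh * kw)
    xmat = x.data.reshape(n, cin, hi * wi)
    cols = np.matmul(wmat.T, xmat)
    out_data = _col2im(cols, (n, cout, ho, wo), kh, kw, stride, pad)
    if b is not None:
        out_data += b.data.reshape(1, cout, 1, 1)
    prev = (x, w) if b is None else (x, w, b)

    def backward(g):
        gcols, _, _ = _im2col(g, kh, kw, stride, pad)
        if x.requires_grad:
            gx = np.matmul(wmat, gcols)
            x._accumulate(gx.reshape(x.data.shape))
        if w.requires_grad:
            gw = np.matmul(xmat, gcols.transpose(0, 2, 1)).sum(axis=0)
            w._accumulate(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))

    return Tensor._make(out_data, prev, backward)
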
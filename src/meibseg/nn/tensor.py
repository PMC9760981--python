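"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray`` and records
the operations applied to it; :meth:`Tensor.backward` walks the recorded graph
in reverse topological order and accumulates gradients.  Only the operations
needed by an encoder--decoder segmentation CNN are provided (elementwise
arithmetic with broadcasting, reductions, ReLU, 2-D convolution with stride /
padding / dilation, max-pooling, bilinear upsampling, channel concatenation).

All gradients are exercised by finite-difference checks in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "max_pool2d",
    "upsample_bilinear2d",
    "relu",
    "softmax_channels",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the adjoint of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_prev", "_backward")

    def __init__(self, data, requires_grad: bool = False, _prev=(), _backward=None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._prev = tuple(_prev)
        self._backward = _backward

    # -- graph bookkeeping -------------------------------------------------
    @staticmethod
    def _result(data, parents, backward):
        needs = any(p.requires_grad or p._prev for p in parents)
        if not needs:
            return Tensor(data)
        return Tensor(data, requires_grad=False, _prev=parents, _backward=backward)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep graphs would overflow recursion
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
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, dtype={self.data.dtype})"

    # -- elementwise arithmetic (broadcasting) -----------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        out_data = self.data + other.data

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accumulate(-g)

        return Tensor._result(-self.data, (self,), backward)

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(np.asarray(other, dtype=self.data.dtype)) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        out_data = self.data * other.data

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=self.data.dtype))
        out_data = self.data / other.data

        def backward(g):
            self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            other._accumulate(_unbroadcast(-g * self.data / other.data**2, other.data.shape))

        return Tensor._result(out_data, (self, other), backward)

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            self._accumulate(g * exponent * self.data ** (exponent - 1))

        return Tensor._result(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            self._accumulate(g * 0.5 / np.sqrt(self.data))

        return Tensor._result(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accumulate(g * out_data)

        return Tensor._result(out_data, (self,), backward)

    def abs(self):
        out_data = np.abs(self.data)

        def backward(g):
            self._accumulate(g * np.sign(self.data))

        return Tensor._result(out_data, (self,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape).copy())

        return Tensor._result(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        original = self.data.shape

        def backward(g):
            self._accumulate(g.reshape(original))

        return Tensor._result(out_data, (self,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out_data = np.where(mask, x.data, 0)

    def backward(g):
        x._accumulate(g * mask)

    return Tensor._result(out_data, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return Tensor._result(out_data, tuple(tensors), backward)


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 1 of an (N, C, H, W) tensor.

    The max-shift is detached; softmax is shift-invariant so the gradient of
    the computed expression equals the gradient of the exact softmax.
    """
    shift = x - Tensor(x.data.max(axis=1, keepdims=True))
    e = shift.exp()
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Spatial ops on (N, C, H, W) tensors
# ---------------------------------------------------------------------------


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, *,
           stride: int = 1, padding: int = 0, dilation: int = 1) -> Tensor:
    """2-D cross-correlation; x (N,Ci,H,W), weight (Co,Ci,kh,kw)."""
    n, ci, h, w = x.data.shape
    co, ci_w, kh, kw = weight.data.shape
    if ci != ci_w:
        raise ValueError(f"channel mismatch: input {ci}, weight {ci_w}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - dilation * (kh - 1) - 1) // stride + 1
    wo = (wp - dilation * (kw - 1) - 1) // stride + 1
    out = np.zeros((n, co, ho, wo), dtype=x.data.dtype)
    # accumulate one kernel tap at a time: each tap is a strided slice + GEMM
    for ki in range(kh):
        for kj in range(kw):
            patch = xp[:, :, ki * dilation: ki * dilation + stride * ho: stride,
                       kj * dilation: kj * dilation + stride * wo: stride]
            out += np.einsum("oc,bchw->bohw", weight.data[:, :, ki, kj], patch,
                             optimize=True)
    if bias is not None:
        out = out + bias.data.reshape(1, co, 1, 1)

    def backward(g):
        gxp = np.zeros_like(xp)
        gw = np.zeros_like(weight.data)
        for ki in range(kh):
            for kj in range(kw):
                rs = slice(ki * dilation, ki * dilation + stride * ho, stride)
                cs = slice(kj * dilation, kj * dilation + stride * wo, stride)
                patch = xp[:, :, rs, cs]
                gw[:, :, ki, kj] = np.einsum("bohw,bchw->oc", g, patch,
                                             optimize=True)
                gxp[:, :, rs, cs] += np.einsum(
                    "oc,bohw->bchw", weight.data[:, :, ki, kj], g, optimize=True)
        weight._accumulate(gw)
        if padding:
            gx = gxp[:, :, padding:hp - padding, padding:wp - padding]
        else:
            gx = gxp
        x._accumulate(gx)
        if bias is not None:
            bias._accumulate(g.sum(axis=(0, 2, 3)))

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor._result(out, parents, backward)


def max_pool2d(x: Tensor, *, kernel_size: int = 3, stride: int = 2,
               padding: int = 1) -> Tensor:
    n, c, h, w = x.data.shape
    neg = np.finfo(x.data.dtype).min if np.issubdtype(x.data.dtype, np.floating) else np.iinfo(x.data.dtype).min
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=neg)
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kernel_size) // stride + 1
    wo = (wp - kernel_size) // stride + 1
    k2 = kernel_size * kernel_size
    stacked = np.empty((k2, n, c, ho, wo), dtype=x.data.dtype)
    idx = 0
    for ki in range(kernel_size):
        for kj in range(kernel_size):
            stacked[idx] = xp[:, :, ki: ki + stride * ho: stride,
                              kj: kj + stride * wo: stride]
            idx += 1
    arg = stacked.argmax(axis=0)
    out = np.take_along_axis(stacked, arg[None], axis=0)[0]

    def backward(g):
        gxp = np.zeros_like(xp)
        idx = 0
        for ki in range(kernel_size):
            for kj in range(kernel_size):
                mask = arg == idx
                gxp[:, :, ki: ki + stride * ho: stride,
                    kj: kj + stride * wo: stride] += g * mask
                idx += 1
        if padding:
            gxp = gxp[:, :, padding:hp - padding, padding:wp - padding]
        x._accumulate(gxp)

    return Tensor._result(out, (x,), backward)


def _bilinear_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Interpolation matrix mapping a length-n_in axis to n_out (align_corners=False)."""
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    m = np.zeros((n_out, n_in), dtype=dtype)
    m[np.arange(n_out), lo] += 1 - frac
    m[np.arange(n_out), hi] += frac
    return m


def upsample_bilinear2d(x: Tensor, scale_factor: int = 2) -> Tensor:
    n, c, h, w = x.data.shape
    my = _bilinear_matrix(h, h * scale_factor, x.data.dtype)
    mx = _bilinear_matrix(w, w * scale_factor, x.data.dtype)
    out = np.einsum("yh,bchw,xw->bcyx", my, x.data, mx, optimize=True)

    def backward(g):
        # exact adjoint of the separable linear map
        x._accumulate(np.einsum("yh,bcyx,xw->bchw", my, g, mx, optimize=True))

    return Tensor._result(out, (x,), backward)
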
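"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based autograd: a :class:`Tensor` wraps an
``ndarray`` and records, for every operation, a closure that propagates the
output gradient to the operation's inputs.  The operation set is exactly what
the convolutional networks in this package need — elementwise arithmetic with
broadcasting, matrix multiplication, 2-D convolution (im2col + BLAS),
2x2 max pooling, nearest-neighbour upsampling, the usual pointwise
nonlinearities and reductions.

All floating arrays default to float32; float64 inputs are preserved, which
the finite-difference gradient checks in the test-suite rely on.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

__all__ = ["Tensor", "as_tensor"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def _corr2d(x: np.ndarray, w: np.ndarray, stride: int, padding,
            return_col: bool = False):
    """Raw batched cross-correlation via im2col + matmul (no autograd)."""
    n, c, _, _ = x.shape
    f, _, kh, kw = w.shape
    ph, pw = padding if isinstance(padding, tuple) else (padding, padding)
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    oh = (x.shape[2] - kh) // stride + 1
    ow = (x.shape[3] - kw) // stride + 1
    view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]              # N,C,OH,OW,KH,KW
    col = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5))
    col = col.reshape(n * oh * ow, c * kh * kw)
    out = col @ w.reshape(f, c * kh * kw).T
    out = np.ascontiguousarray(out.reshape(n, oh, ow, f).transpose(0, 3, 1, 2))
    return (out, col) if return_col else out


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        self.data: np.ndarray = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad = self.grad + grad

    @staticmethod
    def _make(data: np.ndarray, parents: Iterable["Tensor"], backward) -> "Tensor":
        parents = tuple(p for p in parents if p.requires_grad)
        out = Tensor(data, requires_grad=bool(parents))
        if parents:
            out._parents = parents
            out._backward = backward
        return out

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs here can be thousands of nodes deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accumulate(-g)

        return Tensor._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(-g * a.data / (b.data * b.data), b.shape))

        return Tensor._make(a.data / b.data, (a, b), backward)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        a = self
        p = float(exponent)

        def backward(g):
            a._accumulate(g * p * np.power(a.data, p - 1.0))

        return Tensor._make(np.power(a.data, p), (a,), backward)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accumulate(g @ b.data.T)
            if b.requires_grad:
                b._accumulate(a.data.T @ g)

        return Tensor._make(a.data @ b.data, (a, b), backward)

    # ------------------------------------------------------------- pointwise
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def backward(g):
            a._accumulate(g * out_data)

        return Tensor._make(out_data, (a,), backward)

    def log(self):
        a = self

        def backward(g):
            a._accumulate(g / a.data)

        return Tensor._make(np.log(a.data), (a,), backward)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def backward(g):
            a._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (a,), backward)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def backward(g):
            a._accumulate(g * (1.0 - out_data * out_data))

        return Tensor._make(out_data, (a,), backward)

    def sigmoid(self):
        a = self
        out_data = 1.0 / (1.0 + np.exp(-a.data))

        def backward(g):
            a._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (a,), backward)

    def relu(self):
        a = self
        mask = a.data > 0

        def backward(g):
            a._accumulate(g * mask)

        return Tensor._make(a.data * mask, (a,), backward)

    def leaky_relu(self, slope: float = 0.2):
        a = self
        mask = a.data > 0
        scale = np.where(mask, 1.0, slope).astype(a.data.dtype)

        def backward(g):
            a._accumulate(g * scale)

        return Tensor._make(a.data * scale, (a,), backward)

    def abs(self):
        a = self
        sign = np.sign(a.data)

        def backward(g):
            a._accumulate(g * sign)

        return Tensor._make(np.abs(a.data), (a,), backward)

    def clamp(self, lo: float, hi: float):
        a = self
        mask = ((a.data > lo) & (a.data < hi)).astype(a.data.dtype)

        def backward(g):
            a._accumulate(g * mask)

        return Tensor._make(np.clip(a.data, lo, hi), (a,), backward)

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                axes = tuple(ax % a.ndim for ax in axes)
                g = np.expand_dims(g, tuple(sorted(axes)))
            a._accumulate(np.broadcast_to(g, a.shape))

        return Tensor._make(out_data, (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            count = int(np.prod([self.shape[ax % self.ndim] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # ------------------------------------------------------------- structural
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def backward(g):
            a._accumulate(g.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

        return Tensor._make(a.data[idx], (a,), backward)

    # ------------------------------------------------------ conv / pool / up
    def conv2d(self, weight: "Tensor", bias: "Tensor | None" = None,
               stride: int = 1, padding: int = 0):
        """2-D convolution (cross-correlation), NCHW input, OIHW weight.

        The input gradient is computed as a transposed convolution (dilate
        the output gradient, correlate with the flipped weight) so both
        directions go through one im2col + BLAS matmul.
        """
        a, w = self, weight
        n, c, h, ww = a.shape
        f, cin, kh, kw = w.shape
        if cin != c:
            raise ValueError(f"conv2d channel mismatch: input {c}, weight {cin}")
        out, col = _corr2d(a.data, w.data, stride, padding, return_col=True)
        if bias is not None:
            out += bias.data[None, :, None, None]
        oh, ow = out.shape[2], out.shape[3]

        def backward(g):
            if w.requires_grad or bias is not None and bias.requires_grad:
                g2 = np.ascontiguousarray(
                    g.transpose(0, 2, 3, 1)).reshape(n * oh * ow, f)
                if w.requires_grad:
                    w._accumulate((g2.T @ col).reshape(w.shape))
                if bias is not None and bias.requires_grad:
                    bias._accumulate(g2.sum(axis=0))
            if a.requires_grad:
                if stride > 1:
                    gd = np.zeros((n, f, (oh - 1) * stride + 1,
                                   (ow - 1) * stride + 1), dtype=g.dtype)
                    gd[:, :, ::stride, ::stride] = g
                else:
                    gd = g
                wt = np.ascontiguousarray(
                    w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
                full = _corr2d(gd, wt, 1, (kh - 1, kw - 1))
                # strided convs may not cover the last padded rows/cols
                hp, wp = h + 2 * padding, ww + 2 * padding
                dxp = full
                if full.shape[2] < hp or full.shape[3] < wp:
                    dxp = np.zeros((n, c, hp, wp), dtype=full.dtype)
                    dxp[:, :, :full.shape[2], :full.shape[3]] = full
                if padding:
                    dxp = dxp[:, :, padding:-padding, padding:-padding]
                a._accumulate(dxp)

        parents = (a, w) if bias is None else (a, w, bias)
        return Tensor._make(out, parents, backward)

    def max_pool2d(self):
        """2x2 max pooling with stride 2 (even spatial dims required)."""
        a = self
        n, c, h, w = a.shape
        if h % 2 or w % 2:
            raise ValueError("max_pool2d requires even spatial dimensions")
        v = a.data.reshape(n, c, h // 2, 2, w // 2, 2)
        v = v.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
        idx = v.argmax(axis=-1)
        out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            dv = np.zeros_like(v)
            np.put_along_axis(dv, idx[..., None], g[..., None], axis=-1)
            dv = dv.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
            a._accumulate(dv.reshape(n, c, h, w))

        return Tensor._make(out, (a,), backward)

    def upsample2x(self):
        """Nearest-neighbour 2x spatial upsampling."""
        a = self
        n, c, h, w = a.shape
        out = a.data.repeat(2, axis=2).repeat(2, axis=3)

        def backward(g):
            a._accumulate(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        return Tensor._make(out, (a,), backward)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)
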
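"""Minimal reverse-mode automatic differentiation over numpy arrays.

A small tape-based engine carrying exactly the operations the reconstruction
network and end-to-end loss need: elementwise arithmetic, ReLU, zero-padded
3×3-style convolution (im2col + BLAS matmul), 2× average pooling, 2× nearest
upsampling, channel concatenation and reductions. Tensors hold float32 or
float64 data; gradients match the input dtype.

Layout convention for images: (B, C, H, W).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "conv2d", "relu", "avg_pool2", "upsample2", "concat",
           "mean", "total_sum", "sqrt"]


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    # -- graph mechanics ---------------------------------------------------

    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- ops ---------------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def __add__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = backward
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other, self.data.dtype))

    def __rsub__(self, other):
        return _as_tensor(other, self.data.dtype) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other, self.data.dtype)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = backward
        return out

    __rmul__ = __mul__

    def __truediv__(self, scalar):
        if isinstance(scalar, Tensor):
            raise TypeError("division only supported by constants")
        return self * (1.0 / scalar)

    def square(self):
        out = Tensor(self.data ** 2, parents=(self,))
        out._backward = lambda g: self._accumulate(2.0 * self.data * g)
        return out

    def item(self) -> float:
        return float(self.data)


def _as_tensor(x, dtype) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(np.asarray(x, dtype=dtype))


def _unbroadcast(grad, shape):
    """Sum a gradient down to ``shape`` (reverse numpy broadcasting)."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, 0.0), parents=(x,))
    out._backward = lambda g: x._accumulate(np.where(mask, g, 0.0))
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-size 2-D convolution with zero padding, stride 1.

    x: (B, C, H, W); w: (O, C, kh, kw) with odd kh, kw; b: (O,).
    """
    bsz, cin, h, wd = x.data.shape
    cout, cin2, kh, kw = w.data.shape
    if cin != cin2:
        raise ValueError(f"channel mismatch: input {cin}, weight {cin2}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kh, kw), axis=(2, 3))  # B,C,H,W,kh,kw
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(bsz * h * wd, cin * kh * kw)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out_data = (cols @ wmat.T).reshape(bsz, h, wd, cout).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(np.ascontiguousarray(out_data), parents=parents)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(bsz * h * wd, cout)
        if w.requires_grad:
            gw = (gmat.T @ cols).reshape(cout, cin, kh, kw)
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = gmat @ wmat  # (BHW, C*kh*kw)
            gcols = gcols.reshape(bsz, h, wd, cin, kh, kw)
            gx = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gx[:, :, i:i + h, j:j + wd] += gcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            x._accumulate(gx[:, :, ph:ph + h, pw:pw + wd]
                          if ph or pw else gx)

    out._backward = backward
    return out


def avg_pool2(x: Tensor) -> Tensor:
    """2×2 average pooling; spatial dims must be even."""
    bsz, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"avg_pool2 needs even spatial dims, got {h}x{w}")
    out_data = x.data.reshape(bsz, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
    out = Tensor(out_data, parents=(x,))

    def backward(g):
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0
        x._accumulate(gx)

    out._backward = backward
    return out


def upsample2(x: Tensor) -> Tensor:
    """2× nearest-neighbour upsampling."""
    out = Tensor(np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3),
                 parents=(x,))

    def backward(g):
        bsz, c, h, w = x.data.shape
        gx = g.reshape(bsz, c, h, 2, w, 2).sum(axis=(3, 5))
        x._accumulate(gx)

    out._backward = backward
    return out


def concat(a: Tensor, b: Tensor) -> Tensor:
    """Concatenate along the channel axis."""
    ca = a.data.shape[1]
    out = Tensor(np.concatenate([a.data, b.data], axis=1), parents=(a, b))

    def backward(g):
        a._accumulate(g[:, :ca])
        b._accumulate(g[:, ca:])

    out._backward = backward
    return out


def total_sum(x: Tensor) -> Tensor:
    out = Tensor(np.asarray(x.data.sum()), parents=(x,))
    out._backward = lambda g: x._accumulate(np.broadcast_to(g, x.data.shape).copy())
    return out


def mean(x: Tensor) -> Tensor:
    n = x.data.size
    out = Tensor(np.asarray(x.data.mean()), parents=(x,))
    out._backward = lambda g: x._accumulate(
        np.broadcast_to(g / n, x.data.shape).copy()
    )
    return out


def sqrt(x: Tensor) -> Tensor:
    root = np.sqrt(x.data)
    out = Tensor(root, parents=(x,))
    out._backward = lambda g: x._accumulate(g / np.maximum(2.0 * root, 1e-30))
    return out
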
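"""A small reverse-mode automatic-differentiation engine on numpy arrays.

The stain-translation networks in this package are modest (a patch-embedded
transformer encoder, a transposed-convolution decoder and a small CNN
discriminator), and training at desk scale values bit-level reproducibility
over throughput, so the models run on plain float64 numpy via this engine:
a :class:`Tensor` wraps an ndarray, records the operations applied to it,
and :meth:`Tensor.backward` accumulates gradients by reverse topological
traversal.  Broadcasting follows numpy semantics; gradients of broadcast
operands are summed back to the operand shape.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import as_strided
from scipy.special import erf as _erf

__all__ = ["Tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple = ()

    # -- graph plumbing ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, prev, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in prev):
            out.requires_grad = True
            out._prev = tuple(p for p in prev if p.requires_grad)
            out._backward = backward
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            if t.grad is None:      # persistent grads accumulate across calls
                t.grad = np.zeros_like(t.data)
        self.grad = self.grad + np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic -------------------------------------------------------
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g, other.shape)
        return self._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            self.grad += -g
        return self._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g * other.data, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(g * self.data, other.shape)
        return self._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)

        def bw(g):
            if self.requires_grad:
                self.grad += _unbroadcast(g / other.data, self.shape)
            if other.requires_grad:
                other.grad += _unbroadcast(-g * self.data / other.data**2,
                                           other.shape)
        return self._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, k: float):
        def bw(g):
            self.grad += g * k * self.data ** (k - 1)
        return self._make(self.data ** k, (self,), bw)

    def __matmul__(self, other):
        other = self._coerce(other)

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self.grad += _unbroadcast(ga, self.shape)
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other.grad += _unbroadcast(gb, other.shape)
        return self._make(np.matmul(self.data, other.data), (self, other), bw)

    # -- elementwise nonlinearities --------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bw(g):
            self.grad += g * out_data
        return self._make(out_data, (self,), bw)

    def log(self):
        def bw(g):
            self.grad += g / self.data
        return self._make(np.log(self.data), (self,), bw)

    def tanh(self):
        out_data = np.tanh(self.data)

        def bw(g):
            self.grad += g * (1.0 - out_data**2)
        return self._make(out_data, (self,), bw)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bw(g):
            self.grad += g * out_data * (1.0 - out_data)
        return self._make(out_data, (self,), bw)

    def erf(self):
        def bw(g):
            self.grad += g * (2.0 / np.sqrt(np.pi)) * np.exp(-self.data**2)
        return self._make(_erf(self.data), (self,), bw)

    def gelu(self):
        """Exact-erf GELU: ``x * Phi(x) = 0.5 x (1 + erf(x / sqrt(2)))``."""
        return self * ((self * (1.0 / np.sqrt(2.0))).erf() + 1.0) * 0.5

    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, slope)

        def bw(g):
            self.grad += g * mask
        return self._make(self.data * mask, (self,), bw)

    def abs(self):
        sign = np.sign(self.data)

        def bw(g):
            self.grad += g * sign
        return self._make(np.abs(self.data), (self,), bw)

    # -- reductions and shape ops ----------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bw(g):
            if axis is None:
                self.grad += np.broadcast_to(g, self.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self.grad += np.broadcast_to(gg, self.shape)
        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        old = self.shape

        def bw(g):
            self.grad += g.reshape(old)
        return self._make(self.data.reshape(*shape), (self,), bw)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bw(g):
            self.grad += g.transpose(inv)
        return self._make(self.data.transpose(axes), (self,), bw)

    def softmax(self, axis: int = -1):
        """Numerically stable softmax (the max shift is exact, not approximate)."""
        shifted = self - Tensor(self.data.max(axis=axis, keepdims=True))
        e = shifted.exp()
        return e / e.sum(axis=axis, keepdims=True)

    # -- padding / striding primitives for convolutions ------------------
    def pad2d(self, p: int):
        """Zero-pad the last two axes by ``p`` on each side."""
        if p == 0:
            return self
        width = [(0, 0)] * (self.ndim - 2) + [(p, p), (p, p)]

        def bw(g):
            sl = (Ellipsis, slice(p, -p), slice(p, -p))
            self.grad += g[sl]
        return self._make(np.pad(self.data, width), (self,), bw)

    def dilate2d(self, stride: int):
        """Insert ``stride - 1`` zeros between entries of the last two axes."""
        if stride == 1:
            return self
        *lead, h, w = self.shape
        out_data = np.zeros((*lead, (h - 1) * stride + 1, (w - 1) * stride + 1))
        out_data[..., ::stride, ::stride] = self.data

        def bw(g):
            self.grad += g[..., ::stride, ::stride]
        return self._make(out_data, (self,), bw)

    def flip2d(self):
        def bw(g):
            self.grad += g[..., ::-1, ::-1]
        return self._make(self.data[..., ::-1, ::-1].copy(), (self,), bw)

    # -- convolution ------------------------------------------------------
    def conv2d(self, weight: "Tensor", stride: int = 1, padding: int = 0):
        """2-D cross-correlation: ``self`` (B,C,H,W) with ``weight`` (O,C,k,k)."""
        x, w = self, weight
        b, c, h, wd = x.shape
        o, c2, kh, kw = w.shape
        if c != c2:
            raise ValueError("channel mismatch in conv2d")
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
        ho = (h + 2 * padding - kh) // stride + 1
        wo = (wd + 2 * padding - kw) // stride + 1
        sb, sc, sh, sw = xp.strides
        patches = as_strided(xp, (b, c, kh, kw, ho, wo),
                             (sb, sc, sh, sw, sh * stride, sw * stride))
        out_data = np.einsum("ockl,bcklhw->bohw", w.data, patches, optimize=True)

        def bw(g):
            if w.requires_grad:
                w.grad += np.einsum("bohw,bcklhw->ockl", g, patches, optimize=True)
            if x.requires_grad:
                gp = np.einsum("ockl,bohw->bcklhw", w.data, g, optimize=True)
                gxp = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gxp[:, :, i:i + stride * ho:stride,
                            j:j + stride * wo:stride] += gp[:, :, i, j]
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                x.grad += gxp
        return self._make(out_data, (x, w), bw)

    def conv_transpose2d(self, weight: "Tensor", stride: int = 2, padding: int = 1):
        """Transposed convolution (the adjoint of :meth:`conv2d`).

        ``self`` is (B,C,H,W) and ``weight`` (C,O,k,k); output spatial size
        is ``(H-1)*stride + k - 2*padding``.  Implemented exactly as
        zero-dilation followed by a full correlation with the spatially
        flipped, axis-swapped kernel, so gradients come from the same
        primitives.
        """
        k = weight.shape[2]
        wt = weight.flip2d().transpose(1, 0, 2, 3)
        return self.dilate2d(stride).pad2d(k - 1 - padding).conv2d(wt)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"


class Adam:
    """Adam optimizer (bias-corrected first/second moments)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-5,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = np.zeros_like(p.data)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
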
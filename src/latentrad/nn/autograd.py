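"""A minimal reverse-mode automatic differentiation engine on numpy arrays.

Supports exactly the operations the volumetric networks in this package
need: broadcasting arithmetic, matmul, pointwise nonlinearities, reductions,
reshaping/concatenation, 3D convolution (im2col), 2x average pooling and
nearest-neighbour upsampling.  Arrays are float32 throughout; gradients are
accumulated on a topologically sorted tape.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum-reduce a broadcast gradient back to the operand's shape."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- graph machinery ---------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
            # free graph references as we go
        for t in topo:
            t._parents = ()
            t._backward = None

    def _accum(self, g):
        if not self.requires_grad:
            return
        g = g.astype(DTYPE, copy=False)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def zero_grad(self):
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))
        out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(-g)
        return out

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))
        out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out = Tensor(self.data / other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                      other.data.shape))
        out._backward = bwd
        return out

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * p * self.data ** (p - 1))
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad, (self, other))

        def bwd(g):
            ga = g @ np.swapaxes(other.data, -1, -2)
            gb = np.swapaxes(self.data, -1, -2) @ g
            self._accum(_unbroadcast(ga, self.data.shape))
            other._accum(_unbroadcast(gb, other.data.shape))
        out._backward = bwd
        return out

    __matmul__ = matmul

    # -- pointwise ---------------------------------------------------------

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * val)
        return out

    def log(self):
        out = Tensor(np.log(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g / self.data)
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * 0.5 / val)
        return out

    def abs(self):
        out = Tensor(np.abs(self.data), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * np.sign(self.data))
        return out

    def leaky_relu(self, alpha: float = 0.01):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, alpha * self.data),
                     self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * np.where(mask, 1.0, alpha).astype(DTYPE))
        return out

    def relu(self):
        return self.leaky_relu(0.0)

    def sigmoid(self):
        val = 1.0 / (1.0 + np.exp(-np.clip(self.data, -30, 30)))
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * val * (1.0 - val))
        return out

    def softplus(self):
        x = self.data
        val = np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0)
        sig = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        out = Tensor(val, self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g * sig)
        return out

    # -- reductions & shape ------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad, (self,))

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).astype(DTYPE))
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(gg, self.data.shape).astype(DTYPE))
        out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), self.requires_grad, (self,))
        out._backward = lambda g: self._accum(g.reshape(self.data.shape))
        return out

    def transpose(self, axes):
        out = Tensor(self.data.transpose(axes), self.requires_grad, (self,))
        inv = np.argsort(axes)
        out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], self.requires_grad, (self,))

        def bwd(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accum(full)
        out._backward = bwd
        return out


def concat(tensors, axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, any(t.requires_grad for t in tensors), tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(a, b)
            t._accum(g[tuple(idx)])
    out._backward = bwd
    return out


def avg_pool3d(x: Tensor, factor: int = 2) -> Tensor:
    """Non-overlapping average pooling over the three trailing spatial axes."""
    n, c, d, h, w = x.data.shape
    f = factor
    view = x.data.reshape(n, c, d // f, f, h // f, f, w // f, f)
    out_data = view.mean(axis=(3, 5, 7))
    out = Tensor(out_data, x.requires_grad, (x,))

    def bwd(g):
        gg = g[:, :, :, None, :, None, :, None] / float(f ** 3)
        gg = np.broadcast_to(gg, (n, c, d // f, f, h // f, f, w // f, f))
        x._accum(gg.reshape(n, c, d, h, w).astype(DTYPE))
    out._backward = bwd
    return out


def upsample_nearest3d(x: Tensor, factor: int = 2) -> Tensor:
    n, c, d, h, w = x.data.shape
    f = factor
    out_data = x.data.repeat(f, axis=2).repeat(f, axis=3).repeat(f, axis=4)
    out = Tensor(out_data, x.requires_grad, (x,))

    def bwd(g):
        gg = g.reshape(n, c, d, f, h, f, w, f).sum(axis=(3, 5, 7))
        x._accum(gg.astype(DTYPE))
    out._backward = bwd
    return out


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded 3D convolution (stride 1, odd cubic kernel) via im2col."""
    n, cin, d, h, wd = x.data.shape
    f, cin2, kd, kh, kw = w.data.shape
    assert cin == cin2, "channel mismatch"
    pd_, ph, pw = kd // 2, kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pd_, pd_), (ph, ph), (pw, pw)))
    win = sliding_window_view(xp, (kd, kh, kw), axis=(2, 3, 4))
    # (n, cin, d, h, w, kd, kh, kw) -> (n, P, cin*k^3)
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(n, d * h * wd, cin * kd * kh * kw)
    cols = np.ascontiguousarray(cols, dtype=DTYPE)
    w2 = w.data.reshape(f, -1)
    out_data = cols @ w2.T  # (n, P, f)
    if b is not None:
        out_data = out_data + b.data[None, None, :]
    out_data = out_data.transpose(0, 2, 1).reshape(n, f, d, h, wd)
    parents = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data, any(p.requires_grad for p in parents), parents)

    def bwd(g):
        g2 = g.reshape(n, f, d * h * wd).transpose(0, 2, 1)  # (n, P, f)
        if w.requires_grad:
            gw = np.einsum("npf,npk->fk", g2, cols, optimize=True)
            w._accum(gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g2.sum(axis=(0, 1)))
        if x.requires_grad:
            dcols = g2 @ w2  # (n, P, cin*k^3)
            dcols = dcols.reshape(n, d, h, wd, cin, kd, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kd):
                for j in range(kh):
                    for l in range(kw):
                        dxp[:, :, i:i + d, j:j + h, l:l + wd] += \
                            dcols[:, :, :, :, :, i, j, l].transpose(0, 4, 1, 2, 3)
            x._accum(dxp[:, :, pd_:pd_ + d, ph:ph + h, pw:pw + wd])
    out._backward = bwd
    return out
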
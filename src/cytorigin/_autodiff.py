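"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the package's networks need: broadcasting
arithmetic, (batched) matrix products, the usual pointwise nonlinearities,
reductions, indexing/concatenation, and 2-D convolution / max-pooling via
im2col.  Everything is float64 and deterministic.  Gradients are accumulated
by topological traversal of the recorded graph, micrograd-style but
vectorized over arrays.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "softmax", "log_softmax", "SGD", "Adam"]


def _as_array(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float64)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over added leading axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum over axes that were broadcast from size 1
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = tuple(_prev)

    # ------------------------------------------------------------- helpers
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def _track(self, out_data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(out_data, requires_grad=req, _prev=parents if req else ())
        if req:
            out._backward = backward
        return out

    # ---------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._track(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._track(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._track(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / other.data**2, other.shape))

        return self._track(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._track(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if a.ndim == 1 and b.ndim == 1:  # inner product
                if self.requires_grad:
                    self._accum(g * b)
                if other.requires_grad:
                    other._accum(g * a)
                return
            if a.ndim == 1:  # (k,) @ (..., k, n) -> (..., n)
                ga = (g[..., None, :] @ np.swapaxes(b, -1, -2))[..., 0, :]
                gb = a[:, None] @ g[..., None, :]
            elif b.ndim == 1:  # (..., m, k) @ (k,) -> (..., m)
                ga = g[..., :, None] @ b[None, :]
                gb = (np.swapaxes(a, -1, -2) @ g[..., :, None])[..., 0]
            else:
                ga = g @ np.swapaxes(b, -1, -2)
                gb = np.swapaxes(a, -1, -2) @ g
            if self.requires_grad:
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(gb, other.shape))

        return self._track(out_data, (self, other), backward)

    # ------------------------------------------------------------ pointwise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._track(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._track(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return self._track(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return self._track(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._track(out_data, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._track(self.data * mask, (self,), backward)

    # ----------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            g = np.asarray(g)
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())

        return self._track(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # ---------------------------------------------------------------- shape
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        orig = self.shape

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(orig))

        return self._track(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        axes = axes or None
        out_data = self.data.transpose(axes) if axes else self.data.T
        inv = np.argsort(axes) if axes else None

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv) if inv is not None else g.T)

        return self._track(out_data, (self,), backward)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._track(out_data, (self,), backward)

    # -------------------------------------------------------------- conv/pool
    def conv2d(self, weight: "Tensor", bias: "Tensor" = None, stride: int = 1, padding: int = 0):
        """2-D convolution.  self: (C_in, H, W); weight: (C_out, C_in, kh, kw)."""
        x, w = self.data, weight.data
        c_in, h, wd = x.shape
        c_out, _, kh, kw = w.shape
        xp = np.pad(x, ((0, 0), (padding, padding), (padding, padding)))
        windows = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(1, 2))
        windows = windows[:, ::stride, ::stride]  # (C_in, H_out, W_out, kh, kw)
        h_out, w_out = windows.shape[1], windows.shape[2]
        col = windows.transpose(1, 2, 0, 3, 4).reshape(h_out * w_out, c_in * kh * kw)
        wmat = w.reshape(c_out, -1)
        out_data = (col @ wmat.T).T.reshape(c_out, h_out, w_out)
        if bias is not None:
            out_data = out_data + bias.data[:, None, None]

        parents = (self, weight) + ((bias,) if bias is not None else ())

        def backward(g):
            gmat = g.reshape(c_out, -1).T  # (H_out*W_out, C_out)
            if weight.requires_grad:
                weight._accum((gmat.T @ col).reshape(w.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(1, 2)))
            if self.requires_grad:
                gcol = gmat @ wmat  # (H_out*W_out, C_in*kh*kw)
                gcol = gcol.reshape(h_out, w_out, c_in, kh, kw)
                gx = np.zeros_like(xp)
                for i in range(kh):
                    for j in range(kw):
                        gx[:, i : i + h_out * stride : stride, j : j + w_out * stride : stride] += (
                            gcol[:, :, :, i, j].transpose(2, 0, 1)
                        )
                self._accum(gx[:, padding : padding + h, padding : padding + wd])

        return self._track(out_data, parents, backward)

    def maxpool2d(self, k: int = 2):
        """Non-overlapping k×k max pooling over (C, H, W); trailing rows/cols dropped."""
        c, h, w = self.data.shape
        ho, wo = h // k, w // k
        x = self.data[:, : ho * k, : wo * k].reshape(c, ho, k, wo, k)
        out_data = x.max(axis=(2, 4))
        # argmax mask for backward
        mask = x == out_data[:, :, None, :, None]
        # break ties: keep first max only
        flat = mask.reshape(c, ho, k, wo, k)

        def backward(g):
            if not self.requires_grad:
                return
            gx = np.zeros((c, h, w))
            spread = flat * g[:, :, None, :, None]
            counts = flat.sum(axis=(2, 4), keepdims=True)
            spread = spread / counts
            gx[:, : ho * k, : wo * k] = spread.reshape(c, ho * k, wo * k)
            self._accum(gx)

        return self._track(out_data, (self,), backward)

    # ------------------------------------------------------------- backward
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64).reshape(self.data.shape)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


# ----------------------------------------------------------------- functions
def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    req = any(t.requires_grad for t in tensors)
    out = Tensor(out_data, requires_grad=req, _prev=tuple(tensors) if req else ())

    if req:

        def backward(g):
            splits = np.cumsum(sizes)[:-1]
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)

        out._backward = backward
    return out


def stack(tensors, axis: int = 0) -> Tensor:
    expanded = []
    for t in tensors:
        t = Tensor._lift(t)
        shape = list(t.shape)
        shape.insert(axis if axis >= 0 else t.ndim + 1 + axis, 1)
        expanded.append(t.reshape(*shape))
    return concat(expanded, axis=axis)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


# ----------------------------------------------------------------- optimizers
class SGD:
    """SGD with classical momentum and decoupled L2 weight decay."""

    def __init__(self, params, lr: float, momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.momentum = float(momentum)
        self.weight_decay = float(weight_decay)
        self._buf = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, buf in zip(self.params, self._buf):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            buf *= self.momentum
            buf += g
            p.data -= self.lr * buf


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = float(weight_decay)
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self._t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self._t)
            vhat = v / (1 - self.b2**self._t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
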
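"""Small neural-network layer library on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor

__all__ = ["Module", "Linear", "LayerNorm", "Embedding", "Conv2d", "MLP"]


class Module:
    """Base class: parameter discovery, state dicts, gradient reset."""

    def parameters(self):
        out = []
        for value in vars(self).values():
            out.extend(_collect(value))
        return out

    def named_state(self, prefix=""):
        state = {}
        for name, value in vars(self).items():
            _collect_named(value, f"{prefix}{name}", state)
        return state

    def state_dict(self):
        return {k: v.data.copy() for k, v in self.named_state().items()}

    def load_state_dict(self, state):
        named = self.named_state()
        if set(named) != set(state):
            raise KeyError("state dict keys do not match module parameters")
        for k, t in named.items():
            t.data = np.array(state[k], dtype=np.float64)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _collect(value):
    if isinstance(value, Tensor):
        return [value] if value.requires_grad else []
    if isinstance(value, Module):
        return value.parameters()
    if isinstance(value, (list, tuple)):
        out = []
        for v in value:
            out.extend(_collect(v))
        return out
    if isinstance(value, dict):
        out = []
        for v in value.values():
            out.extend(_collect(v))
        return out
    return []


def _collect_named(value, name, state):
    if isinstance(value, Tensor):
        state[name] = value
    elif isinstance(value, Module):
        for k, v in value.named_state().items():
            state[f"{name}.{k}"] = v
    elif isinstance(value, (list, tuple)):
        for i, v in enumerate(value):
            _collect_named(v, f"{name}.{i}", state)
    elif isinstance(value, dict):
        for k, v in value.items():
            _collect_named(v, f"{name}.{k}", state)


class Linear(Module):
    """Affine map for row-vector inputs: y = x @ W + b, W of shape (d_in, d_out)."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        bound = 1.0 / np.sqrt(d_in)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(d_in, d_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered / (var + self.eps).sqrt() * self.gamma + self.beta


class Embedding(Module):
    """Lookup table mapping integer ids to learned vectors."""

    def __init__(self, n: int, dim: int, rng: np.random.Generator, scale: float = 0.02):
        self.table = Tensor(rng.normal(0.0, scale, size=(n, dim)), requires_grad=True)

    def forward(self, idx) -> Tensor:
        return self.table[int(idx)]


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        bound = 1.0 / np.sqrt(c_in * k * k)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(c_out, c_in, k, k)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class ChannelNorm2d(Module):
    """Per-channel spatial normalization with learnable affine parameters.

    Normalizes each channel map of a (C, H, W) activation over its spatial
    extent — a batch-independent stand-in for batch normalization that keeps
    single-example training deterministic."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones((channels, 1, 1)), requires_grad=True)
        self.beta = Tensor(np.zeros((channels, 1, 1)), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        c, h, w = x.shape
        flat = x.reshape(c, h * w)
        mu = flat.mean(axis=1, keepdims=True)
        centered = flat - mu
        var = (centered * centered).mean(axis=1, keepdims=True)
        normed = (centered / (var + self.eps).sqrt()).reshape(c, h, w)
        return normed * self.gamma + self.beta


class MLP(Module):
    """Two-layer perceptron with ReLU between the linear maps."""

    def __init__(self, d_in: int, d_hidden: int, d_out: int, rng: np.random.Generator):
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())
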
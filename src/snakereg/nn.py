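"""Lightweight layer / parameter containers and the Adam optimizer.

Follows the familiar module pattern: layers register parameters and
sub-modules by attribute assignment, ``parameters()`` walks the tree, and
``state_dict`` / ``load_state_dict`` (de)serialize flat name->array maps.
All parameters are float32.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(isinstance(v, Module) for v in value):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, extra={sorted(extra)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, din: int, dout: int, rng: np.random.Generator, bias: bool = True,
                 zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((din, dout))
        else:
            bound = np.sqrt(6.0 / (din + dout))
            w = rng.uniform(-bound, bound, size=(din, dout))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(dout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = ad.matmul(x, self.weight)
        if self.bias is not None:
            out = ad.add(out, self.bias)
        return out


class Conv3d(Module):
    """3x3x3 (or k^3) convolution, stride 1, 'same' padding by default."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, k: int = 3,
                 padding: int | None = None, bias: bool = True, zero_init: bool = False):
        super().__init__()
        self.padding = (k - 1) // 2 if padding is None else padding
        fan_in = cin * k**3
        if zero_init:
            w = np.zeros((cout, cin, k, k, k))
        else:
            bound = np.sqrt(1.0 / fan_in)
            w = rng.uniform(-bound, bound, size=(cout, cin, k, k, k))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(cout)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ad.conv3d(x, self.weight, self.bias, padding=self.padding)


class ChannelNorm3d(Module):
    """Per-channel normalization over the spatial axes of (C, D, H, W).

    This is what batch normalization computes at batch size 1 (the training
    batch size used throughout); no running statistics are kept.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones((channels, 1, 1, 1)))
        self.bias = Parameter(np.zeros((channels, 1, 1, 1)))

    def forward(self, x: Tensor) -> Tensor:
        mu = ad.tmean(x, axis=(1, 2, 3), keepdims=True)
        xc = x - mu
        var = ad.tmean(ad.mul(xc, xc), axis=(1, 2, 3), keepdims=True)
        inv = ad.power(ad.add(var, self.eps), -0.5)
        return ad.add(ad.mul(ad.mul(xc, inv), self.weight), self.bias)


class GroupNorm3d(Module):
    def __init__(self, channels: int, groups: int = 4, eps: float = 1e-5):
        super().__init__()
        while channels % groups:
            groups -= 1
        self.groups = groups
        self.eps = eps
        self.weight = Parameter(np.ones((channels, 1, 1, 1)))
        self.bias = Parameter(np.zeros((channels, 1, 1, 1)))

    def forward(self, x: Tensor) -> Tensor:
        C, D, H, W = x.shape
        g = self.groups
        xg = ad.reshape(x, (g, C // g * D * H * W))
        mu = ad.tmean(xg, axis=1, keepdims=True)
        xc = xg - mu
        var = ad.tmean(ad.mul(xc, xc), axis=1, keepdims=True)
        inv = ad.power(ad.add(var, self.eps), -0.5)
        xn = ad.reshape(ad.mul(xc, inv), (C, D, H, W))
        return ad.add(ad.mul(xn, self.weight), self.bias)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.weight, self.bias, self.eps)


def make_norm3d(kind: str, channels: int) -> Module:
    if kind == "batch":
        return ChannelNorm3d(channels)
    if kind == "group":
        return GroupNorm3d(channels)
    raise ValueError(f"unknown norm kind {kind!r}")


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: list[Parameter], lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * (g * g)
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
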
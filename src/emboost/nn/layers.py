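"""Module system and layers for the enhancement network."""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor

__all__ = [
    "Module",
    "ModuleList",
    "Parameter",
    "Linear",
    "Conv3d",
    "ConvTranspose3d",
    "GroupNorm",
    "BatchNorm3d",
    "Dropout",
    "LeakyReLU",
    "Sequential",
]


def Parameter(data: np.ndarray) -> Tensor:
    return Tensor(data, requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self) -> None:
        self.training = True

    def forward(self, *args, **kwargs):
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(f"{full}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # buffers (running stats) live in _buffers dicts on the layers that need them
    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        buffers = getattr(self, "_buffers", {})
        for name, value in buffers.items():
            yield f"{prefix}{name}", value
        for name, child in self._children():
            yield from child.named_buffers(f"{prefix}{name}.")

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"buffer:{name}": b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        expected = set(params) | {f"buffer:{n}" for n in buffers}
        if expected != set(state):
            missing = expected - set(state)
            extra = set(state) - expected
            raise ValueError(f"state dict mismatch; missing={sorted(missing)[:5]}, extra={sorted(extra)[:5]}")
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data[...] = state[name]
        for name, b in buffers.items():
            b[...] = state[f"buffer:{name}"]


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._modules = list(modules)

    def __iter__(self):
        return iter(self._modules)

    def __len__(self):
        return len(self._modules)

    def __getitem__(self, i):
        return self._modules[i]

    def append(self, m: Module) -> None:
        self._modules.append(m)

    def _children(self):
        for i, m in enumerate(self._modules):
            yield str(i), m

    def named_parameters(self, prefix: str = ""):
        for i, m in enumerate(self._modules):
            yield from m.named_parameters(f"{prefix}{i}.")

    def named_buffers(self, prefix: str = ""):
        for i, m in enumerate(self._modules):
            yield from m.named_buffers(f"{prefix}{i}.")

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules:
            m.train(mode)
        return self


class Sequential(ModuleList):
    def forward(self, x: Tensor) -> Tensor:
        for m in self._modules:
            x = m(x)
        return x


def _fan_in_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = 1.0 / math.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


def _trunc_normal(rng: np.random.Generator, shape: tuple[int, ...], std: float = 0.02) -> np.ndarray:
    x = rng.normal(0.0, std, size=shape)
    return np.clip(x, -2 * std, 2 * std).astype(np.float32)


class Linear(Module):
    """y = x W^T + b over the last axis; truncated-normal init."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(_trunc_normal(rng, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight.swapaxes(0, 1)
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv3d(Module):
    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int | None = None,
        bias: bool = True,
    ):
        super().__init__()
        if pad is None:
            pad = kernel // 2
        self.stride = stride
        self.pad = pad
        fan_in = in_ch * kernel**3
        self.weight = Parameter(_fan_in_uniform(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in))
        self.bias = Parameter(_fan_in_uniform(rng, (out_ch,), fan_in)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv3d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ConvTranspose3d(Module):
    """Kernel-2 / stride-2 transposed convolution (exact spatial doubling)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        fan_in = in_ch * 8
        self.weight = Parameter(_fan_in_uniform(rng, (in_ch, out_ch, 2, 2, 2), fan_in))
        self.bias = Parameter(_fan_in_uniform(rng, (out_ch,), fan_in)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose3d_s2(x, self.weight, self.bias)


class GroupNorm(Module):
    """Normalize over channel groups and all spatial positions (batch-free)."""

    def __init__(self, num_groups: int, num_channels: int, eps: float = 1e-5):
        super().__init__()
        if num_channels % num_groups:
            raise ValueError(f"channels {num_channels} not divisible by groups {num_groups}")
        self.groups = num_groups
        self.eps = eps
        self.weight = Parameter(np.ones(num_channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        spatial = x.shape[2:]
        xg = x.reshape(b, self.groups, -1)
        mu = xg.mean(axis=2, keepdims=True)
        xc = xg - mu
        var = (xc * xc).mean(axis=2, keepdims=True)
        xn = xc / (var + self.eps).sqrt()
        xn = xn.reshape(b, c, *spatial)
        shape = (1, c) + (1,) * len(spatial)
        return xn * self.weight.reshape(shape) + self.bias.reshape(shape)


class BatchNorm3d(Module):
    """Batch normalization over (batch, spatial) with running statistics."""

    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(num_channels, dtype=np.float32))
        self.bias = Parameter(np.zeros(num_channels, dtype=np.float32))
        self._buffers = {
            "running_mean": np.zeros(num_channels, dtype=np.float32),
            "running_var": np.ones(num_channels, dtype=np.float32),
        }

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        shape = (1, c, 1, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3, 4), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3, 4), keepdims=True)
            m = self.momentum
            rm, rv = self._buffers["running_mean"], self._buffers["running_var"]
            rm *= 1 - m
            rm += m * mu.data.reshape(c)
            rv *= 1 - m
            rv += m * var.data.reshape(c)
            xn = xc / (var + self.eps).sqrt()
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(shape))
            var = Tensor(self._buffers["running_var"].reshape(shape))
            xn = (x - mu) / (var + self.eps).sqrt()
        return xn * self.weight.reshape(shape) + self.bias.reshape(shape)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return F.dropout(x, self.p, self.rng, self.training)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)
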
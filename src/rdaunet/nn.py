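"""Layers and optimiser for the segmentation network.

Provides a small ``Module`` hierarchy (parameters, buffers, train/eval
mode, state dicts) plus the layers the model needs: static and dynamic
2-D convolutions, batch normalisation, a stride-2 transposed convolution
and a fully connected layer, together with an Adam optimiser.

A dynamic convolution holds K parallel kernels and a squeeze-style
attention MLP that maps the globally pooled input to K logits; a
temperature-scaled softmax turns these into a convex combination, the
kernels are aggregated per sample, and a single convolution with the
aggregated kernel is applied.
"""

from __future__ import annotations

import math
import random as _random
from typing import Iterator

import numpy as np

from . import _tensor as T
from ._tensor import Tensor

__all__ = [
    "set_global_seed", "get_rng", "Parameter", "Module", "Conv2d",
    "DynamicConv2d", "BatchNorm2d", "ConvTranspose2x", "Linear", "Adam",
]

_rng = np.random.default_rng(0)


def set_global_seed(seed: int) -> None:
    """Seed every stochastic component: weight init, shuffling, NumPy legacy."""
    global _rng
    _rng = np.random.default_rng(int(seed))
    np.random.seed(int(seed) % (2 ** 32))
    _random.seed(int(seed))


def get_rng() -> np.random.Generator:
    return _rng


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class: attribute-walking parameter registry, train/eval mode."""

    def __init__(self):
        self.training = True
        self._buffers: dict[str, np.ndarray] = {}

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, v in vars(self).items():
            if isinstance(v, Module):
                yield name, v
            elif isinstance(v, (list, tuple)):
                for i, m in enumerate(v):
                    if isinstance(m, Module):
                        yield f"{name}.{i}", m

    def modules(self) -> Iterator["Module"]:
        yield self
        for _, child in self._children():
            yield from child.modules()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, v in vars(self).items():
            if isinstance(v, Parameter):
                yield prefix + name, v
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, v in self._buffers.items():
            yield prefix + name, v
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": p.data.copy() for k, p in self.named_parameters()}
        state.update({f"buffer:{k}": b.copy() for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                params[name].data = np.asarray(value, dtype=np.float32).reshape(
                    params[name].shape)
            else:
                owner = self
                *path, leaf = name.split(".")
                for part in path:
                    if isinstance(owner, (list, tuple)):
                        owner = owner[int(part)]
                    else:
                        owner = getattr(owner, part)
                owner._buffers[leaf] = np.asarray(value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def _kaiming(shape: tuple, fan_in: int, rng: np.random.Generator) -> np.ndarray:
    std = math.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, stride: int = 1,
                 padding: int = 0, dilation: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or get_rng()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_kaiming((out_ch, in_ch, kernel, kernel), fan_in, rng))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, dilation=self.dilation)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, *, zero_init: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or get_rng()
        if zero_init:
            w = np.zeros((in_f, out_f), dtype=np.float32)
        else:
            w = _kaiming((in_f, out_f), in_f, rng)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_f))

    def forward(self, x: Tensor) -> Tensor:
        return T.matmul(x, self.weight) + self.bias


class DynamicConv2d(Module):
    """Convolution whose kernel is an input-conditioned convex combination
    of K learned kernels (kernel attention via a pooled two-layer MLP).

    The attention's final layer is zero-initialised so training starts from
    the uniform combination; ``temperature`` softens the softmax and is
    typically annealed from a large value towards 1 during training.
    """

    def __init__(self, in_ch: int, out_ch: int, kernel: int, *, K: int = 4,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 temperature: float = 30.0, reduction: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if K < 1:
            raise ValueError("dynamic convolution needs K >= 1 kernels")
        rng = rng or get_rng()
        self.K = K
        self.out_ch, self.in_ch, self.kernel = out_ch, in_ch, kernel
        self.stride, self.padding, self.dilation = stride, padding, dilation
        self.temperature = float(temperature)
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(
            _kaiming((K, out_ch, in_ch, kernel, kernel), fan_in, rng))
        self.bias = Parameter(np.zeros((K, out_ch)))
        hidden = max(in_ch // reduction, 4)
        self.att_fc1 = Linear(in_ch, hidden, rng=rng)
        self.att_fc2 = Linear(hidden, K, zero_init=True, rng=rng)

    def attention(self, x: Tensor) -> Tensor:
        """Kernel-attention weights pi(x), one probability row per sample."""
        pooled = T.tmean(x, axis=(2, 3))                      # (B, C)
        logits = self.att_fc2(T.relu(self.att_fc1(pooled)))   # (B, K)
        return T.softmax(logits, axis=1, temperature=self.temperature)

    def forward(self, x: Tensor) -> Tensor:
        B = x.shape[0]
        pi = self.attention(x)                                # (B, K)
        w_flat = T.reshape(self.weight, (self.K, -1))         # (K, OCkk)
        w_agg = T.reshape(T.matmul(pi, w_flat),
                          (B, self.out_ch, self.in_ch, self.kernel, self.kernel))
        b_agg = T.matmul(pi, self.bias)                       # (B, O)
        out = T.conv2d(x, w_agg, stride=self.stride, padding=self.padding,
                       dilation=self.dilation)
        return out + T.reshape(b_agg, (B, self.out_ch, 1, 1))


class BatchNorm2d(Module):
    def __init__(self, channels: int, *, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        C = x.shape[1]
        if self.training:
            mu = T.tmean(x, axis=(0, 2, 3), keepdims=True)
            var = T.tmean((x - mu) ** 2.0, axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu.data.reshape(C))
            n = x.data.size / C
            unbiased = var.data.reshape(C) * (n / max(n - 1, 1))
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * unbiased)
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(1, C, 1, 1))
            var = Tensor(self._buffers["running_var"].reshape(1, C, 1, 1))
        xhat = (x - mu) * (var + self.eps) ** -0.5
        w = T.reshape(self.weight, (1, C, 1, 1))
        b = T.reshape(self.bias, (1, C, 1, 1))
        return xhat * w + b


class ConvTranspose2x(Module):
    """Stride-2, 2x2-kernel transposed convolution: exact spatial doubling."""

    def __init__(self, in_ch: int, out_ch: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or get_rng()
        self.weight = Parameter(_kaiming((in_ch, out_ch, 2, 2), in_ch * 4, rng))
        self.bias = Parameter(np.zeros(out_ch))

    def forward(self, x: Tensor) -> Tensor:
        return T.conv_transpose2x(x, self.weight, self.bias)


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
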
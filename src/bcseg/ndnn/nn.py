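"""Layer and container classes over the autodiff core.

Initialization is Kaiming fan-in normal for convolution weights (gain for
ReLU), zero biases, BN scale 1 / shift 0; every layer takes the
``numpy.random.Generator`` that drives it, so builds are bit-reproducible
given a seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor

DTYPE = np.float32


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(DTYPE)


class Module:
    """Base class with recursive parameter discovery and train/eval modes."""

    def __init__(self):
        self.training = True

    def forward(self, *args):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args):
        return self.forward(*args)

    def _children(self) -> Iterator["Module"]:
        for v in vars(self).values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, ModuleList):
                yield from v

    def parameters(self) -> Iterator[Tensor]:
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                yield v
        for child in self._children():
            yield from child.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for k, v in vars(self).items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield f"{prefix}{k}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{k}.")
            elif isinstance(v, ModuleList):
                for i, m in enumerate(v):
                    yield from m.named_parameters(f"{prefix}{k}.{i}.")

    def train(self) -> "Module":
        self.training = True
        for c in self._children():
            c.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for c in self._children():
            c.eval()
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- state (de)serialization ------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        for name, buf in self.named_buffers():
            state[name] = buf
        return state

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for k, v in vars(self).items():
            if isinstance(v, Module):
                yield from v.named_buffers(f"{prefix}{k}.")
            elif isinstance(v, ModuleList):
                for i, m in enumerate(v):
                    yield from m.named_buffers(f"{prefix}{k}.{i}.")
            elif isinstance(v, np.ndarray) and k.startswith("running_"):
                yield f"{prefix}{k}", v

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=p.data.dtype, copy=True)
        for name, buf in self.named_buffers():
            buf[...] = state[name]

    def copy_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}


class ModuleList(list):
    """A list whose Module elements are visible to parameter discovery."""


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("Conv2d supports odd kernels only (same padding)")
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Tensor(_kaiming(rng, (out_channels, in_channels, kernel_size, kernel_size), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=DTYPE), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias)


class DepthwiseConv2d(Module):
    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        fan_in = kernel_size * kernel_size
        self.weight = Tensor(_kaiming(rng, (channels, kernel_size, kernel_size), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.depthwise_conv2d(x, self.weight, self.bias)


class TransposedConv2x2(Module):
    """Stride-2 transposed convolution: learned exact x2 upsampling."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Tensor(_kaiming(rng, (in_channels, out_channels, 2, 2), in_channels * 4),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=DTYPE), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.transposed_conv2x2(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.weight = Tensor(np.ones(channels, dtype=DTYPE), requires_grad=True)
        self.bias = Tensor(np.zeros(channels, dtype=DTYPE), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return ag.batchnorm2d(x, self.weight, self.bias, self.running_mean,
                              self.running_var, self.training, self.momentum, self.eps)
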
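"""Neural-network module system built on the autodiff core.

Mirrors the familiar Module/parameter idiom: layers register parameters
and submodules via attribute assignment, ``parameters()`` walks the tree,
and ``train()``/``eval()`` toggle batch-norm behaviour.  A lightweight
profiling hook on :class:`Conv2d` records per-layer multiply–accumulate
counts during a forward pass for the FLOPs profiler.
"""

from __future__ import annotations

import contextlib
import math
from typing import Iterator

import numpy as np
from .core import Tensor, batch_norm, conv2d, max_pool2d, upsample_nearest2x

__all__ = [
    "Module", "Sequential", "Identity", "Conv2d", "BatchNorm2d",
    "Upsample", "MaxPool2d", "Activation", "ACTIVATIONS", "profile_macs",
    "seed_all",
]

_PROFILE: list | None = None

_GLOBAL_RNG = np.random.default_rng(0)


def seed_all(seed: int) -> None:
    """Reset the default weight-initialisation stream."""
    global _GLOBAL_RNG
    _GLOBAL_RNG = np.random.default_rng(seed)


@contextlib.contextmanager
def profile_macs():
    """Collect ``(module, macs)`` pairs for every Conv2d forward in the block."""
    global _PROFILE
    prev, _PROFILE = _PROFILE, []
    try:
        yield _PROFILE
    finally:
        _PROFILE = prev


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Tensor]:
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for k, p in self._params.items():
            yield (f"{prefix}{k}", p)
        for k, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{k}.")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # checkpointing -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: p.data.copy() for k, p in self.named_parameters()}
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                out[f"{name}.running_mean"] = m.running_mean.copy()
                out[f"{name}.running_var"] = m.running_var.copy()
        return out

    def load_state_dict(self, sd: dict[str, np.ndarray]) -> None:
        for k, p in self.named_parameters():
            p.data = np.asarray(sd[k], dtype=np.float32).reshape(p.shape)
        for name, m in self._named_modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean[:] = sd[f"{name}.running_mean"]
                m.running_var[:] = sd[f"{name}.running_var"]

    def _named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield (prefix.rstrip("."), self)
        for k, m in self._modules.items():
            yield from m._named_modules(f"{prefix}{k}.")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def __iter__(self):
        return iter(self.mods)

    def __len__(self):
        return len(self.mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


# -- activations ---------------------------------------------------------

def silu(x: Tensor) -> Tensor:
    """Swish-1 / SiLU: x * sigmoid(x)."""
    return x.silu_()


def gelu(x: Tensor) -> Tensor:
    """Gaussian Error Linear Unit, exact form x * Phi(x)."""
    return x.gelu_()


def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    return x.maximum(x * slope)


def relu(x: Tensor) -> Tensor:
    return x.maximum(0.0)


def hard_sigmoid(x: Tensor) -> Tensor:
    """Piecewise-linear sigmoid approximation relu6(x+3)/6 (mobile nets)."""
    return ((x + 3.0).clamp(0.0, 6.0)) * (1.0 / 6.0)


def hard_swish(x: Tensor) -> Tensor:
    return x * hard_sigmoid(x)


ACTIVATIONS = {
    "silu": silu,
    "swish1": silu,
    "gelu": gelu,
    "leaky_relu": leaky_relu,
    "relu": relu,
    "hard_swish": hard_swish,
    "none": lambda x: x,
}


class Activation(Module):
    def __init__(self, kind: str = "silu"):
        super().__init__()
        if kind not in ACTIVATIONS:
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x):
        return ACTIVATIONS[self.kind](x)


# -- core layers ---------------------------------------------------------

class Conv2d(Module):
    def __init__(self, c1: int, c2: int, k: int = 1, s: int = 1,
                 p: int | None = None, groups: int = 1, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if p is None:
            p = k // 2
        self.c1, self.c2, self.k, self.s, self.p, self.groups = c1, c2, k, s, p, groups
        rng = rng or _GLOBAL_RNG
        fan_in = c1 // groups * k * k
        scale = math.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, (c2, c1 // groups, k, k)), requires_grad=True)
        self.bias = Tensor(np.zeros(c2), requires_grad=True) if bias else None
        if bias:
            self._params["bias"] = self.bias

    def forward(self, x):
        if _PROFILE is not None:
            n, _, h, w = x.shape
            oh = (h + 2 * self.p - self.k) // self.s + 1
            ow = (w + 2 * self.p - self.k) // self.s + 1
            # h' * w' * k * k * c/g * n_out per image
            _PROFILE.append(
                (self, oh * ow * self.k * self.k * (self.c1 // self.groups) * self.c2))
        return conv2d(x, self.weight, self.bias, self.s, self.p, self.groups)


class BatchNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.c, self.eps, self.momentum = c, eps, momentum
        self.weight = Tensor(np.ones(c), requires_grad=True)
        self.bias = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x):
        if _PROFILE is not None:
            # normalisation cost: affine rescale + shift, 2 MAC-equivalents
            # per element (the convention of the common FLOPs profilers)
            _PROFILE.append((self, 2 * x.size))
        return batch_norm(x, self.weight, self.bias, self.running_mean,
                          self.running_var, self.training, self.momentum, self.eps)


class MaxPool2d(Module):
    def __init__(self, k: int, s: int = 1, p: int | None = None):
        super().__init__()
        self.k, self.s, self.p = k, s, p

    def forward(self, x):
        return max_pool2d(x, self.k, self.s, self.p)


class Upsample(Module):
    """Nearest-neighbour 2x upsampling."""

    def __init__(self, scale: int = 2):
        super().__init__()
        if scale != 2:
            raise ValueError("only 2x nearest upsampling is supported")

    def forward(self, x):
        return upsample_nearest2x(x)
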
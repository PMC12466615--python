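"""Building blocks of the detector: Conv+BN+SiLU, C2f, SPPF, heads.

Module system conventions: a :class:`Module` discovers parameters and
sub-modules from its attributes; convolutions carry no bias (normalization
provides the affine), the two 1x1 projection convs at the end of each
detection branch do carry bias.  Channel widths follow the nano scaling:
base ladder (64, 128, 256, 512, 1024) x width_mult, rounded up to a
multiple of 8.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import (Tensor, batch_norm, concat, conv2d, max_pool2d, silu,
                       upsample_nearest2x)


class Module:
    """Minimal module base: recursive parameter discovery, train/eval mode."""

    def __init__(self):
        self.training = True

    @staticmethod
    def _children(value, name):
        """Yield (name, module) pairs from an attribute, descending nested lists."""
        if isinstance(value, Module):
            yield name, value
        elif isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                yield from Module._children(item, f"{name}.{i}")

    def modules(self):
        yield self
        for name, v in self.__dict__.items():
            for _, child in Module._children(v, name):
                yield from child.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            if isinstance(v, Tensor) and v.requires_grad:
                yield f"{prefix}{name}", v
            elif isinstance(v, (Module, list, tuple)):
                for cname, child in Module._children(v, name):
                    yield from child.named_parameters(f"{prefix}{cname}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def buffers(self):
        """Non-trainable state (fixed projections, running statistics)."""
        for m in self.modules():
            for name, v in m.__dict__.items():
                if isinstance(v, np.ndarray):
                    yield m, name, v
                elif isinstance(v, Tensor) and not v.requires_grad:
                    yield m, name, v.data

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- (de)serialization ----------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, (m, name, buf) in enumerate(self.buffers()):
            state[f"__buf{i}__{name}"] = buf.copy()
        return state

    def load_state_dict(self, state: dict):
        for name, p in self.named_parameters():
            p.data[...] = state[name]
        for i, (m, name, buf) in enumerate(self.buffers()):
            buf[...] = state[f"__buf{i}__{name}"]


def kaiming(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    bound = math.sqrt(1.0 / fan_in)
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Conv(Module):
    """3x3/1x1 convolution -> batch norm -> SiLU (the detector's basic cell)."""

    def __init__(self, rng, c1: int, c2: int, k: int = 1, s: int = 1, act: bool = True):
        super().__init__()
        self.c1, self.c2, self.k, self.s = c1, c2, k, s
        self.weight = kaiming(rng, (c2, c1, k, k), c1 * k * k)
        self.gamma = Tensor(np.ones(c2), requires_grad=True)
        self.beta = Tensor(np.zeros(c2), requires_grad=True)
        self.running_mean = np.zeros(c2, dtype=np.float32)
        self.running_var = np.ones(c2, dtype=np.float32)
        self.act = act

    def forward(self, x):
        y = conv2d(x, self.weight, stride=self.s, padding=self.k // 2)
        y = batch_norm(y, self.gamma, self.beta, self.running_mean,
                       self.running_var, self.training)
        return silu(y) if self.act else y


class Conv2dBias(Module):
    """Plain convolution with bias and no normalization (branch projections)."""

    def __init__(self, rng, c1: int, c2: int, k: int = 1):
        super().__init__()
        self.c1, self.c2, self.k, self.s = c1, c2, k, 1
        self.weight = kaiming(rng, (c2, c1, k, k), c1 * k * k)
        self.bias = Tensor(np.zeros(c2), requires_grad=True)

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=1, padding=self.k // 2)


class Bottleneck(Module):
    def __init__(self, rng, c1: int, c2: int, shortcut: bool):
        super().__init__()
        self.cv1 = Conv(rng, c1, c2, 3)
        self.cv2 = Conv(rng, c2, c2, 3)
        self.add = shortcut and c1 == c2

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


class C2f(Module):
    """Cross-stage-partial block: split, run n bottlenecks, merge all paths."""

    def __init__(self, rng, c1: int, c2: int, n: int, shortcut: bool = False):
        super().__init__()
        self.c = c2 // 2
        self.cv1 = Conv(rng, c1, 2 * self.c, 1)
        self.cv2 = Conv(rng, (2 + n) * self.c, c2, 1)
        self.m = [Bottleneck(rng, self.c, self.c, shortcut) for _ in range(n)]

    def forward(self, x):
        y = self.cv1(x)
        parts = [y[:, :self.c], y[:, self.c:]]
        for b in self.m:
            parts.append(b(parts[-1]))
        return self.cv2(concat(parts, axis=1))


class SPPF(Module):
    """Spatial pyramid pooling (fast): three chained 5x5 max-pools."""

    def __init__(self, rng, c1: int, c2: int, k: int = 5):
        super().__init__()
        c = c1 // 2
        self.cv1 = Conv(rng, c1, c, 1)
        self.cv2 = Conv(rng, c * 4, c2, 1)
        self.k = k

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(max_pool2d(y[-1], self.k, 1, self.k // 2))
        return self.cv2(concat(y, axis=1))


class Upsample(Module):
    def forward(self, x):
        return upsample_nearest2x(x)


def scale_channels(base: int, width_mult: float, max_channels: int) -> int:
    """Width scaling: multiply, cap, round up to a multiple of 8."""
    c = min(base, max_channels) * width_mult
    return int(math.ceil(c / 8) * 8)


def scale_depth(base: int, depth_mult: float) -> int:
    return max(round(base * depth_mult), 1)
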
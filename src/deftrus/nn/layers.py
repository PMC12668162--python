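"""Layer/module abstractions over the autodiff tensors.

Modules register parameters and sub-modules on attribute assignment, exactly
so that ``parameters()`` and ``state_dict()`` can walk the tree by name.
Weights are initialized N(0, 0.02), the convention for this generator family;
the RNG is always passed in explicitly so that model construction is
reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor
from . import functional as F

__all__ = [
    "Module", "Sequential", "Conv2d", "Linear", "InstanceNorm2d",
    "ReLU", "LeakyReLU", "Tanh", "Sigmoid", "Upsample2d", "ReflectionPad2d",
    "ResnetBlock",
]

DTYPE = np.float32


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})

    def __setattr__(self, name, value):
        if isinstance(value, Tensor):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def parameters(self):
        for p in self._params.values():
            yield p
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield f"{prefix}{k}", p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix=f"{prefix}{k}.")

    def state_dict(self) -> dict:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters: {sorted(missing)}")
        for k, p in own.items():
            p.data = np.asarray(state[k], dtype=p.data.dtype).reshape(p.data.shape)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _param(rng: np.random.Generator, shape, std: float = 0.02) -> Tensor:
    return Tensor(rng.normal(0.0, std, size=shape).astype(DTYPE), requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0,
                 pad_mode="zeros", bias=True, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.stride = stride
        self.padding = padding
        self.pad_mode = pad_mode
        self.weight = _param(rng, (out_ch, in_ch, kernel, kernel))
        self.bias = Tensor(np.zeros(out_ch, dtype=DTYPE), requires_grad=True) if bias else None

    def forward(self, x):
        if self.padding:
            x = F.pad2d(x, self.padding, self.pad_mode)
        return F.conv2d(x, self.weight, self.bias, stride=self.stride)


class Linear(Module):
    def __init__(self, in_f, out_f, bias=True, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.weight = _param(rng, (in_f, out_f))
        # small random bias: an all-zero input row must not project to the
        # exact zero vector (it would have no direction under cosine sim)
        self.bias = _param(rng, (out_f,)) if bias else None

    def forward(self, x):
        y = x @ self.weight
        return y + self.bias if self.bias is not None else y


class InstanceNorm2d(Module):
    """Non-affine instance norm (the standard choice for these generators)."""

    def __init__(self, num_features=None, eps=1e-5):
        super().__init__()
        self.eps = eps

    def forward(self, x):
        return F.instance_norm2d(x, eps=self.eps)


class ReLU(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x):
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope=0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x):
        return x.tanh()


class Sigmoid(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x):
        return x.sigmoid()


class Upsample2d(Module):
    def __init__(self, factor=2):
        super().__init__()
        self.factor = factor

    def forward(self, x):
        return F.upsample_nearest2d(x, self.factor)


class ReflectionPad2d(Module):
    def __init__(self, pad):
        super().__init__()
        self.pad = pad

    def forward(self, x):
        return F.pad2d(x, self.pad, "reflect")


class ResnetBlock(Module):
    """Two reflect-padded 3x3 convs with instance norm and a skip connection."""

    def __init__(self, channels, rng):
        super().__init__()
        self.conv1 = Conv2d(channels, channels, 3, padding=1, pad_mode="reflect", rng=rng)
        self.norm1 = InstanceNorm2d(channels)
        self.conv2 = Conv2d(channels, channels, 3, padding=1, pad_mode="reflect", rng=rng)
        self.norm2 = InstanceNorm2d(channels)

    def forward(self, x):
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h))
        return x + h
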
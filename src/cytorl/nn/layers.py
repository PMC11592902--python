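"""Parameterised layers on top of the autodiff tensor.

Modules hold :class:`Parameter` leaves and sub-modules as attributes;
``parameters()`` collects them recursively and ``state_dict`` /
``load_state_dict`` round-trip raw arrays for checkpointing.  Initialisation
is driven by an explicit ``numpy.random.Generator`` so two modules built
from the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Tensor, concat

__all__ = [
    "Parameter", "Module", "Linear", "Conv2d", "DepthwiseConv2d", "Conv3dSame",
    "LayerNorm", "LSTMCell", "Sequential",
]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_parameters(self, prefix: str = ""):
        out = []
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out.append((key, value))
            elif isinstance(value, Module):
                out.extend(value.named_parameters(prefix=f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(prefix=f"{key}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{key}.{i}", item))
        return out

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            arr = np.asarray(state[name], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Parameter(_kaiming(rng, (in_dim, out_dim), in_dim))
        self.bias = Parameter(np.zeros(out_dim))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None):
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        self.weight = Parameter(_kaiming(rng, (cout, cin, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class DepthwiseConv2d(Module):
    def __init__(self, c: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: int | None = None):
        self.stride = stride
        self.pad = k // 2 if pad is None else pad
        self.weight = Parameter(_kaiming(rng, (c, k, k), k * k))
        self.bias = Parameter(np.zeros(c))

    def forward(self, x: Tensor) -> Tensor:
        return F.depthwise_conv2d(x, self.weight, self.bias,
                                  stride=self.stride, pad=self.pad)


class Conv3dSame(Module):
    """Single-kernel 3-D same convolution over (N, D, H, W) volumes."""

    def __init__(self, k: tuple[int, int, int], rng: np.random.Generator):
        kd, kh, kw = k
        self.weight = Parameter(_kaiming(rng, (kd, kh, kw), kd * kh * kw))
        self.bias = Parameter(np.zeros(()))

    def forward(self, x: Tensor) -> Tensor:
        return F.conv3d_same(x, self.weight, self.bias)


class LayerNorm(Module):
    """Normalise the last axis to zero mean / unit variance, then affine."""

    def __init__(self, dim: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        normed = centred * (var + self.eps) ** -0.5
        return normed * self.gamma + self.beta

    def normalize(self, x: Tensor) -> Tensor:
        """The pre-affine normalisation (exposed for testing the contract)."""
        mu = x.mean(axis=-1, keepdims=True)
        centred = x - mu
        var = (centred * centred).mean(axis=-1, keepdims=True)
        return centred * (var + self.eps) ** -0.5


class LSTMCell(Module):
    """Standard LSTM cell; gate order i, f, g, o in the stacked weights."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator):
        self.hidden = hidden
        scale = 1.0 / np.sqrt(hidden)
        self.w = Parameter(rng.uniform(-scale, scale, size=(in_dim + hidden, 4 * hidden)))
        self.b = Parameter(np.zeros(4 * hidden))

    def forward(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        z = concat([x, h], axis=-1) @ self.w + self.b
        H = self.hidden
        i = z[:, 0 * H : 1 * H].sigmoid()
        f = z[:, 1 * H : 2 * H].sigmoid()
        g = z[:, 2 * H : 3 * H].tanh()
        o = z[:, 3 * H : 4 * H].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.items = list(modules)

    def forward(self, x):
        for m in self.items:
            x = m(x)
        return x
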
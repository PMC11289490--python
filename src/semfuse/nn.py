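"""Neural-network building blocks over the autograd engine.

Provides the module system (parameter registration, state dicts, train/eval
modes), 2-D convolution with reflective padding, batch normalization with
running statistics, and the Adam optimizer. Layout is NCHW everywhere.
"""

from __future__ import annotations

import hashlib
from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
        self.requires_grad = True  # parameters trainable even under no_grad


class Module:
    """Base class with torch-style attribute registration."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def _set_buffer(self, name: str, value: np.ndarray):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # ------------------------------------------------------------- traversal
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for n, p in self._params.items():
            yield prefix + n, p
        for n, m in self._modules.items():
            yield from m.named_parameters(prefix + n + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for n in self._buffers:
            yield prefix + n, getattr(self, n)
        for n, m in self._modules.items():
            yield from m.named_buffers(prefix + n + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    # ----------------------------------------------------------------- modes
    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # ------------------------------------------------------------------ state
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param.{n}": p.data.copy() for n, p in self.named_parameters()}
        state.update({f"buffer.{n}": b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, name = key.split(".", 1)
            if kind == "param":
                if name not in params:
                    raise KeyError(f"unknown parameter {name!r}")
                params[name].data = np.asarray(value, dtype=np.float64).copy()
            else:
                mod = self
                parts = name.split(".")
                for part in parts[:-1]:
                    mod = mod._modules[part]
                mod._set_buffer(parts[-1], np.asarray(value, dtype=np.float64).copy())

    def state_hash(self) -> str:
        h = hashlib.sha256()
        for name in sorted(self.state_dict()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.state_dict()[name]).tobytes())
        return h.hexdigest()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_init(rng: np.random.Generator, shape: tuple[int, ...],
            fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """3x3 (or kxk) convolution with reflective 'same' padding by default."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, padding: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        fan_in = in_channels * k * k
        self.weight = Parameter(he_init(rng, (out_channels, in_channels, k, k),
                                        fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._set_buffer("running_mean", (1 - m) * self.running_mean
                             + m * mu.data.reshape(c))
            self._set_buffer("running_var", (1 - m) * self.running_var
                             + m * var.data.reshape(c))
        else:
            mu = Tensor(self.running_mean.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.reshape(1, c, 1, 1))
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        gamma = self.gamma.reshape(1, c, 1, 1)
        beta = self.beta.reshape(1, c, 1, 1)
        return xhat * gamma + beta


class ConvBNAct(Module):
    """Conv -> BatchNorm -> LeakyReLU, the fusion network's workhorse."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int = 3,
                 stride: int = 1, slope: float = 0.01,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size, stride,
                           rng=rng)
        self.bn = BatchNorm2d(out_channels)
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).leaky_relu(self.slope)


class Adam:
    """Adam optimizer over a list of parameters."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t,
                "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m, dtype=np.float64).copy() for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float64).copy() for v in state["v"]]
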
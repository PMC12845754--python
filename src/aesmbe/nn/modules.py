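"""Layers and optimizer built on :mod:`aesmbe.nn.tensor`.

Initialization mirrors the uniform fan-in scheme used by mainstream deep
learning frameworks for dense and convolutional layers: weights and biases
are drawn from U(-1/sqrt(fan_in), 1/sqrt(fan_in)) with a caller-supplied
:class:`numpy.random.Generator`, which makes every model in this package a
pure function of its seed.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .tensor import Parameter, Tensor

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "BatchNorm1d",
    "LayerNorm",
    "SGD",
    "uniform_init",
]


def uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Minimal container: tracks sub-modules and parameters by attribute."""

    def __init__(self):
        self._params: dict[str, Parameter] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> Iterator[Parameter]:
        yield from self._params.values()
        for m in self._modules.values():
            yield from m.parameters()

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for n, p in self._params.items():
            yield prefix + n, p
        for mn, m in self._modules.items():
            yield from m.named_parameters(prefix + mn + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {n: p.data.copy() for n, p in self.named_parameters()}
        for mn, m in self._named_modules():
            for bn, buf in m._buffers().items():
                state[f"{mn}{bn}"] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for n, p in self.named_parameters():
            p.data = np.asarray(state[n], dtype=np.float64).copy()
        for mn, m in self._named_modules():
            for bn in m._buffers():
                setattr(m, bn, np.asarray(state[f"{mn}{bn}"], dtype=np.float64).copy())

    def _named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for mn, m in self._modules.items():
            yield from m._named_modules(prefix + mn + ".")

    def _buffers(self) -> dict[str, np.ndarray]:
        return {}


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.weight = Parameter(uniform_init(rng, (in_features, out_features), in_features))
        self.bias = Parameter(uniform_init(rng, (out_features,), in_features)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv1d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        fan_in = in_channels * kernel_size
        self.weight = Parameter(
            uniform_init(rng, (out_channels, in_channels, kernel_size), fan_in)
        )
        self.bias = Parameter(uniform_init(rng, (out_channels,), fan_in)) if bias else None
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv1d(self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm1d(Module):
    """Per-channel normalization over (batch, time) for (N, C, L) inputs.

    Training mode uses batch statistics and updates exponential running
    estimates; eval mode uses the running estimates, so outputs for a fixed
    input are batch-independent after training.
    """

    def __init__(self, num_features: int, eps: float = 1e-4, momentum: float = 0.1):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.eps = eps
        self.momentum = momentum
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def __call__(self, x: Tensor) -> Tensor:
        if x.ndim != 3:
            raise ValueError("BatchNorm1d expects (N, C, L)")
        if self.training:
            mu = x.data.mean(axis=(0, 2))
            var = x.data.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
            # differentiate through the batch statistics
            xm = x - x.mean(axis=(0, 2), keepdims=True)
            var_t = (xm * xm).mean(axis=(0, 2), keepdims=True)
            xhat = xm * (var_t + self.eps) ** -0.5
        else:
            xm = x - self.running_mean[None, :, None]
            xhat = xm * (1.0 / np.sqrt(self.running_var + self.eps))[None, :, None]
        g = self.gamma.reshape(1, -1, 1)
        b = self.beta.reshape(1, -1, 1)
        return xhat * g + b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.gamma, self.beta, eps=self.eps)


class SGD:
    """Stochastic gradient descent with classical momentum.

    ``clip_norm`` optionally rescales the global gradient norm before the
    update, a standard safeguard against the occasional exploding batch.
    """

    def __init__(self, params, lr: float = 1e-4, momentum: float = 0.9,
                 clip_norm: float | None = None):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.clip_norm = clip_norm
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        scale = 1.0
        if self.clip_norm is not None:
            total = np.sqrt(
                sum(float((p.grad**2).sum()) for p in self.params if p.grad is not None)
            )
            if total > self.clip_norm:
                scale = self.clip_norm / (total + 1e-12)
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad * scale
            p.data -= self.lr * v

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
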
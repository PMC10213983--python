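"""Layer and optimizer building blocks on top of the autodiff core.

Conventions follow the 1-D signal layout ``(batch, channels, length)``.
Parameter initialisation is He-uniform for convolutions/linear layers and is
always driven by an explicit ``numpy.random.Generator`` so that training is
reproducible from a single seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, sliding_windows

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "BatchNorm1d",
    "LayerNorm",
    "MaxPool1d",
    "Dropout",
    "Sequential",
    "LeakyReLU",
    "Adam",
]


class Module:
    """Base class: parameter registry, train/eval mode, state dicts."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        object.__setattr__(self, name, t)
        return t

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (prefix + name, p)
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self._named_buffers():
            state[name] = m.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        buffers = dict(self._named_buffers())
        for name, value in state.items():
            if name in own:
                if own[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}")
                own[name].data = np.array(value, dtype=np.float64)
            elif name in buffers:
                self._set_buffer(name, value)
            else:
                raise KeyError(f"unknown parameter {name}")

    # buffers = non-trainable state (batch-norm running stats)
    def _named_buffers(self, prefix: str = ""):
        for name in getattr(self, "_buffer_names", ()):
            yield prefix + name, getattr(self, name)
        for mname, m in self._modules.items():
            yield from m._named_buffers(prefix + mname + ".")

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        parts = dotted.split(".")
        obj = self
        for p in parts[:-1]:
            obj = obj._modules[p]
        object.__setattr__(obj, parts[-1], np.array(value, dtype=np.float64))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.n_in, self.n_out = n_in, n_out
        self.register_parameter("weight", _he_uniform(rng, n_in, (n_in, n_out)))
        self.register_parameter("bias", np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    """1-D convolution (cross-correlation), layout (B, C_in, L).

    ``padding='valid'`` (no padding) or ``'same'`` (stride must be 1).
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        stride: int = 1,
        padding: str = "valid",
        rng: np.random.Generator | None = None,
        bias: bool = True,
    ):
        super().__init__()
        if kernel < 1 or stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        if padding == "same" and stride != 1:
            raise ValueError("same-padding requires stride 1")
        self.c_in, self.c_out, self.kernel, self.stride = c_in, c_out, kernel, stride
        self.padding = padding
        rng = rng if rng is not None else np.random.default_rng(0)
        self.register_parameter(
            "weight", _he_uniform(rng, c_in * kernel, (c_in * kernel, c_out))
        )
        self.has_bias = bias
        if bias:
            self.register_parameter("bias", np.zeros(c_out))

    def out_length(self, length: int) -> int:
        if self.padding == "same":
            return length
        return (length - self.kernel) // self.stride + 1

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {x.shape[1]}")
        if self.padding == "same":
            left = (self.kernel - 1) // 2
            x = x.pad_last(left, self.kernel - 1 - left)
        elif x.shape[-1] < self.kernel:
            raise ValueError(
                f"input length {x.shape[-1]} < kernel {self.kernel}"
            )
        win = sliding_windows(x, self.kernel, self.stride)  # (B, C, n, k)
        n = win.shape[2]
        cols = win.transpose(0, 2, 1, 3).reshape(x.shape[0], n, self.c_in * self.kernel)
        out = cols @ self.weight  # (B, n, c_out)
        if self.has_bias:
            out = out + self.bias
        return out.transpose(0, 2, 1)  # (B, c_out, n)


class BatchNorm1d(Module):
    """Per-channel batch normalisation over (batch, length)."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.register_parameter("gamma", np.ones(channels))
        self.register_parameter("beta", np.zeros(channels))
        object.__setattr__(self, "running_mean", np.zeros(channels))
        object.__setattr__(self, "running_var", np.ones(channels))

    def forward(self, x: Tensor) -> Tensor:
        # x: (B, C, L)
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.reshape(1, -1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        g = self.gamma.reshape(1, self.channels, 1)
        b = self.beta.reshape(1, self.channels, 1)
        return xhat * g + b


class LayerNorm(Module):
    """Normalise over the last axis, then affine."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.dim = dim
        self.eps = eps
        self.register_parameter("gamma", np.ones(dim))
        self.register_parameter("beta", np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        xhat = (x - mu) / (var + self.eps).sqrt()
        return xhat * self.gamma + self.beta

    def normalized(self, x: Tensor) -> Tensor:
        """Pre-affine normalisation (exposed for testing)."""
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / (var + self.eps).sqrt()


class MaxPool1d(Module):
    def __init__(self, kernel: int, stride: int | None = None):
        super().__init__()
        self.kernel = kernel
        self.stride = stride if stride is not None else kernel

    def out_length(self, length: int) -> int:
        return (length - self.kernel) // self.stride + 1

    def forward(self, x: Tensor) -> Tensor:
        win = sliding_windows(x, self.kernel, self.stride)  # (B, C, n, k)
        return win.max(axis=-1)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class Adam:
    """Adam over an explicit parameter list (frozen params are simply not
    handed to the optimizer)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
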
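"""Layers, modules and the Adam optimizer built on :mod:`cslearn.autodiff`.

Modules follow the familiar container pattern: a :class:`Module` owns
parameters (gradient-enabled tensors) and submodules, exposes
``parameters()`` / ``state_dict()`` and a train/eval flag (used by batch
normalization). All initializers take an explicit ``numpy.random.Generator``
so network construction is reproducible.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .autodiff import Tensor, conv2d, conv_transpose2d


class Module:
    def __init__(self):
        self.training = True

    # Parameter discovery walks the instance dict, so assignment order is the
    # canonical parameter order (stable across runs for state_dict/checksum).
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in self.__dict__.values():
            if isinstance(value, Tensor):
                if value._is_param:
                    params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, value in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(value, Tensor):
                state[key] = value.data
            elif isinstance(value, Module):
                state.update(value.named_state(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        state.update(item.named_state(f"{key}.{i}."))
        return state

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_state().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        live = self.named_state()
        if set(live) != set(state):
            raise ValueError("state_dict keys do not match module structure")
        for key, arr in state.items():
            np.copyto(live[key], np.asarray(arr, dtype=np.float64))

    def checksum(self) -> str:
        """SHA-256 over all parameter/buffer bytes in canonical order."""
        h = hashlib.sha256()
        for key in sorted(self.named_state()):
            h.update(key.encode())
            h.update(self.named_state()[key].tobytes())
        return h.hexdigest()

    def train(self, mode: bool = True):
        self.training = mode
        for value in self.__dict__.values():
            if isinstance(value, Module):
                value.train(mode)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        item.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def freeze(self):
        for p in self.parameters():
            p.requires_grad = False
        return self

    def unfreeze(self):
        for p in self.parameters():
            p.requires_grad = True
        return self

    def is_frozen(self) -> bool:
        return all(not p.requires_grad for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


def _param(data: np.ndarray) -> Tensor:
    t = Tensor(data, requires_grad=True)
    t._is_param = True
    return t


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.weight = _param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = _param(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 1,
        pad: int = 0,
        bias: bool = True,
    ):
        super().__init__()
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = _param(rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)))
        self.bias = _param(np.zeros(c_out)) if bias else None
        self.stride = stride
        self.pad = pad

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ConvTranspose2d(Module):
    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int,
        rng: np.random.Generator,
        stride: int = 2,
        pad: int = 1,
    ):
        super().__init__()
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = _param(rng.normal(0.0, scale, size=(c_in, c_out, kernel, kernel)))
        self.bias = _param(np.zeros(c_out))
        self.stride = stride
        self.pad = pad

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    """Batch normalization over (N,H,W) per channel with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = _param(np.ones(channels))
        self.beta = _param(np.zeros(channels))
        self.running_mean = Tensor(np.zeros(channels))
        self.running_var = Tensor(np.ones(channels))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean.data = (1 - m) * self.running_mean.data + m * mu.data.reshape(c)
            self.running_var.data = (1 - m) * self.running_var.data + m * var.data.reshape(c)
        else:
            mu = Tensor(self.running_mean.data.reshape(1, c, 1, 1))
            var = Tensor(self.running_var.data.reshape(1, c, 1, 1))
        xhat = (x - mu) * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape(x.shape[0], int(np.prod(x.shape[1:])))


class AvgPool2d(Module):
    """2x2 average pooling (the only pool size the package needs)."""

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("AvgPool2d expects even spatial dimensions")
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
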
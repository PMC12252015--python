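"""Layer building blocks on top of the autograd tape.

Mirrors the torch.nn surface loosely: a :class:`Module` owns parameters and
submodules discovered through attribute inspection, with ``train()``/``eval()``
modes and recursive ``named_parameters``.  Multiply-accumulate counts are
recorded into an ambient :class:`MacRecorder` when one is active, which is how
the model profiler measures per-layer cost without a symbolic shape pass.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    """A tensor that is trained (``requires_grad`` always on)."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class MacRecorder:
    """Collects (layer name, MAC count) pairs during a profiled forward."""

    _active: "MacRecorder | None" = None

    def __init__(self):
        self.entries: list[tuple[str, int]] = []

    def __enter__(self):
        MacRecorder._active = self
        return self

    def __exit__(self, *exc):
        MacRecorder._active = None

    @classmethod
    def record(cls, name: str, macs: int) -> None:
        if cls._active is not None:
            cls._active.entries.append((name, int(macs)))

    @property
    def total(self) -> int:
        return sum(m for _, m in self.entries)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ----------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix, self
        for name, attr in vars(self).items():
            if isinstance(attr, Module):
                yield from attr.named_modules(f"{prefix}.{name}" if prefix else name)
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        sub = f"{name}.{i}"
                        yield from item.named_modules(f"{prefix}.{sub}" if prefix else sub)

    def named_parameters(self) -> Iterator[tuple[str, Parameter]]:
        for mprefix, mod in self.named_modules():
            for name, attr in vars(mod).items():
                if isinstance(attr, Parameter):
                    yield (f"{mprefix}.{name}" if mprefix else name), attr

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def train(self, mode: bool = True) -> "Module":
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # -- state dict ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for mprefix, mod in self.named_modules():
            for name, attr in vars(mod).items():
                if isinstance(attr, np.ndarray) and name.startswith("running_"):
                    key = f"{mprefix}.{name}" if mprefix else name
                    state[key] = attr.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        buffers = {}
        for mprefix, mod in self.named_modules():
            for name, attr in vars(mod).items():
                if isinstance(attr, np.ndarray) and name.startswith("running_"):
                    buffers[f"{mprefix}.{name}" if mprefix else name] = (mod, name)
        for key, value in state.items():
            if key in own:
                if own[key].shape != value.shape:
                    raise ValueError(f"shape mismatch for {key}")
                own[key].data = value.astype(np.float32).copy()
            elif key in buffers:
                mod, name = buffers[key]
                setattr(mod, name, value.astype(np.float32).copy())
            else:
                raise KeyError(f"unexpected key in state dict: {key}")

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.relu(x)


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.silu(x)


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = True, *, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(
            0.0, std, (out_channels, in_channels // groups, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = ag.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)
        _, _, ho, wo = out.shape
        MacRecorder.record(
            "conv2d",
            self.kernel_size ** 2 * (self.in_channels // self.groups)
            * self.out_channels * ho * wo)
        return out


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 *, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.in_features = in_features
        self.out_features = out_features
        bound = np.sqrt(1.0 / in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = ag.matmul(x, self.weight)
        if self.bias is not None:
            out = ag.add(out, self.bias)
        MacRecorder.record("linear", self.in_features * self.out_features)
        return out


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.num_features = num_features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=np.float32)
        self.running_var = np.ones(num_features, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        return ag.batch_norm(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, training=self.training,
                             momentum=self.momentum, eps=self.eps)


class LayerNorm(Module):
    """Normalizes over the last (channel) axis of a token tensor."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.dim = dim
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        return ag.layer_norm(x, self.gamma, self.beta, eps=self.eps)


class GlobalAvgPool(Module):
    """NCHW -> NC mean pool over the spatial axes."""

    def forward(self, x: Tensor) -> Tensor:
        return ag.mean(x, axis=(2, 3))


NORM_TYPES = (BatchNorm2d, LayerNorm)
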
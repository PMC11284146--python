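"""Module system and standard layers built on the autodiff core."""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor

__all__ = [
    "Module",
    "Sequential",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "LayerNorm2d",
    "Identity",
    "count_parameters",
]


class Module:
    """Minimal container with parameter discovery and state (de)serialisation."""

    def __init__(self):
        self.training = True

    # -- discovery ---------------------------------------------------------
    @staticmethod
    def _walk(name: str, value) -> Iterator[tuple[str, object]]:
        """Yield (name, leaf) for Parameters and Modules in nested containers."""
        if isinstance(value, (Parameter, Module)):
            yield name, value
        elif isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                yield from Module._walk(f"{name}.{i}", item)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, value in vars(self).items():
            for full, leaf in self._walk(f"{prefix}{name}", value):
                if isinstance(leaf, Parameter):
                    yield full, leaf
                else:
                    yield from leaf.named_parameters(f"{full}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def modules(self) -> Iterator["Module"]:
        yield self
        for name, value in vars(self).items():
            for _, leaf in self._walk(name, value):
                if isinstance(leaf, Module):
                    yield from leaf.modules()

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, np.ndarray) and name.startswith("running_"):
                yield full, value
            else:
                for sub, leaf in self._walk(full, value):
                    if isinstance(leaf, Module):
                        yield from leaf.named_buffers(f"{sub}.")

    # -- mode / grads ------------------------------------------------------
    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- state -------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        state.update({name: buf for name, buf in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True):
        """Load arrays by name.  Returns (missing, unexpected) key lists.

        A shape mismatch raises immediately, naming the first offending tensor.
        """
        own = {name: p for name, p in self.named_parameters()}
        bufs = dict(self.named_buffers())
        missing, unexpected = [], []
        for name, arr in state.items():
            target = own.get(name)
            if target is not None:
                if tuple(target.shape) != tuple(arr.shape):
                    raise ValueError(
                        f"shape mismatch for '{name}': "
                        f"checkpoint {tuple(arr.shape)} vs model {tuple(target.shape)}"
                    )
                target.data = np.asarray(arr, dtype=target.dtype)
            elif name in bufs:
                if bufs[name].shape != arr.shape:
                    raise ValueError(
                        f"shape mismatch for buffer '{name}': "
                        f"checkpoint {tuple(arr.shape)} vs model {bufs[name].shape}"
                    )
                bufs[name][...] = arr
            else:
                unexpected.append(name)
        for name in own:
            if name not in state:
                missing.append(name)
        if strict and (missing or unexpected):
            raise KeyError(
                f"state dict mismatch: missing={missing[:5]} unexpected={unexpected[:5]}"
            )
        return missing, unexpected

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


def _kaiming_uniform(rng, shape, fan_in, dtype):
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


def trunc_normal(rng, shape, std=0.02, dtype=np.float32):
    """Normal(0, std) truncated to +-2 std (resampling)."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out.astype(dtype)


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        groups: int = 1,
        bias: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
        init: str = "kaiming",
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = (in_channels // groups) * k * k
        shape = (out_channels, in_channels // groups, k, k)
        if init == "trunc_normal":
            w = trunc_normal(rng, shape, 0.02, dtype)
        else:
            w = _kaiming_uniform(rng, shape, fan_in, dtype)
        self.weight = Parameter(w)
        self.bias = (
            Parameter(
                np.zeros(out_channels, dtype)
                if init == "trunc_normal"
                else _kaiming_uniform(rng, (out_channels,), fan_in, dtype)
            )
            if bias
            else None
        )
        self.stride, self.padding, self.groups = stride, padding, groups

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)


class ConvTranspose2d(Module):
    """Transposed convolution with kernel == stride (checkerboard-free)."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=None,
                 rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        stride = stride or kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Parameter(
            _kaiming_uniform(rng, (in_channels, out_channels, kernel_size, kernel_size),
                             fan_in, dtype)
        )
        self.bias = Parameter(_kaiming_uniform(rng, (out_channels,), fan_in, dtype))
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        super().__init__()
        self.weight = Parameter(np.ones(channels, dtype))
        self.bias = Parameter(np.zeros(channels, dtype))
        self.running_mean = np.zeros(channels, dtype)
        self.running_var = np.ones(channels, dtype)
        self.eps, self.momentum = eps, momentum

    def forward(self, x: Tensor) -> Tensor:
        return F.batch_norm(
            x, self.weight, self.bias, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class LayerNorm2d(Module):
    """LayerNorm over the channel axis of (N, C, H, W) maps."""

    def __init__(self, channels: int, eps: float = 1e-6, dtype=np.float32):
        super().__init__()
        self.weight = Parameter(np.ones(channels, dtype))
        self.bias = Parameter(np.zeros(channels, dtype))
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return F.layer_norm_channels(x, self.weight, self.bias, self.eps)


def count_parameters(module: Module) -> int:
    return sum(p.size for p in module.parameters())
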
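"""Layer abstractions built on the autodiff tensor.

A :class:`Module` owns named parameters and sub-modules discovered by
attribute traversal (insertion order, hence deterministic), which gives the
stable flat name->array mapping used by checkpoints.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from . import functional as F
from .tensor import Tensor


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)
        # Parameters stay trainable even when constructed inside no_grad.
        self.requires_grad = True


def trunc_normal_(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Normal(0, std) clipped to +/- 2 std (near-truncated-normal init)."""
    return np.clip(rng.standard_normal(shape) * std, -2 * std, 2 * std).astype(np.float32)


class Module:
    def __init__(self):
        self.training = True

    # -- traversal --------------------------------------------------------
    def named_members(self, prefix: str = "") -> Iterator[tuple[str, object]]:
        for name, val in vars(self).items():
            if name == "training":
                continue
            path = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield path, val
            elif isinstance(val, Module):
                yield from val.named_members(f"{path}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_members(f"{path}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{path}.{i}", item
            elif isinstance(val, np.ndarray):  # buffers (running stats)
                yield path, val

    def named_parameters(self) -> Iterator[tuple[str, Parameter]]:
        for name, val in self.named_members():
            if isinstance(val, Parameter):
                yield name, val

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for name, val in self.named_members():
            out[name] = val.data.copy() if isinstance(val, Parameter) else val.copy()
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_members())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if missing or extra:
            raise KeyError(f"state mismatch: missing={sorted(missing)}, unexpected={sorted(extra)}")
        for name, val in own.items():
            arr = np.asarray(state[name])
            target = val.data.shape if isinstance(val, Parameter) else val.shape
            if arr.shape != target:
                raise ValueError(f"shape mismatch for {name}")
            if isinstance(val, Parameter):
                val.data = arr.astype(np.float32).copy()
            else:
                val[...] = arr

    # -- mode -------------------------------------------------------------
    def train(self) -> "Module":
        self._set_mode(True)
        return self

    def eval(self) -> "Module":
        self._set_mode(False)
        return self

    def _set_mode(self, training: bool) -> None:
        self.training = training
        for val in vars(self).values():
            if isinstance(val, Module):
                val._set_mode(training)
            elif isinstance(val, (list, tuple)):
                for item in val:
                    if isinstance(item, Module):
                        item._set_mode(training)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    """Affine map on the trailing axis; weight stored as (in, out)."""

    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        self.weight = Parameter(trunc_normal_(rng, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Conv2d(Module):
    """2-D convolution; ``init="kaiming"`` (fan-out, the reference backbone's
    scheme) or ``init="trunc_normal"`` (std 0.02)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, groups: int = 1, bias: bool = True,
                 init: str = "kaiming"):
        super().__init__()
        if in_ch % groups:
            raise ValueError("in_ch must be divisible by groups")
        self.stride, self.padding, self.groups = stride, padding, groups
        shape = (out_ch, in_ch // groups, kernel, kernel)
        if init == "kaiming":
            fan_out = kernel * kernel * out_ch // groups
            std = float(np.sqrt(2.0 / fan_out))
            w = (rng.standard_normal(shape) * std).astype(np.float32)
        else:
            w = trunc_normal_(rng, shape)
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, stride=self.stride,
                        padding=self.padding, groups=self.groups)


class BatchNorm2d(Module):
    """Per-channel normalization over (N, H, W) with running statistics."""

    def __init__(self, num_ch: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(np.ones(num_ch))
        self.beta = Parameter(np.zeros(num_ch))
        self.running_mean = np.zeros(num_ch, dtype=np.float32)
        self.running_var = np.ones(num_ch, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(-1) * (n / max(n - 1, 1))
            self.running_mean += self.momentum * (mu.data.reshape(-1) - self.running_mean)
            self.running_var += self.momentum * (unbiased - self.running_var)
            xn = xc / (var + self.eps).sqrt()
        else:
            mu = self.running_mean[None, :, None, None]
            sd = np.sqrt(self.running_var + self.eps)[None, :, None, None]
            xn = (x - mu) / sd
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xn * g + b


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))

    def forward(self, x: Tensor) -> Tensor:
        return F.layer_norm(x, self.gamma, self.beta, eps=self.eps)


class Dropout(Module):
    """Inverted dropout; identity when p == 0 or in eval mode."""

    def __init__(self, p: float = 0.0, seed: int = 0):
        super().__init__()
        self.p = p
        self._rng = np.random.default_rng(seed)

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = (self._rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * Tensor(keep)
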
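"""Global Channel-Spatial Attention (GCSA).

The block refines an encoder feature map in three stages:

1. **Channel attention** — at every spatial position the C-vector of
   activations is passed through a position-shared two-layer MLP
   (C -> C/4 -> C, ReLU between) and squashed by a sigmoid; the resulting
   per-position channel gate multiplies the input elementwise.
2. **Channel shuffle** — channels are split into 4 groups and the
   (group, within-group) axes are transposed, mixing information across
   groups without touching any value.
3. **Spatial attention** — two 7x7 convolutions (C -> C/4 -> C, each
   followed by batch-norm, ReLU after the first) produce a spatial gate,
   again applied through a sigmoid and an elementwise product.

Both a plain-NumPy functional API (operating on 4-D ``(N, C, H, W)`` arrays
with explicit parameter records) and a differentiable :class:`GCSA` layer are
provided; they share the same convolution kernels and agree numerically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .exceptions import ConfigurationError, ShapeError
from .nn.functional import conv2d_forward
from .nn.tensor import Tensor, _sigmoid


def _check_feature_map(x: np.ndarray, divisor: int = 4) -> None:
    if x.ndim != 4:
        raise ShapeError(f"expected a 4-D (N, C, H, W) feature map, got ndim={x.ndim}")
    n, c, h, w = x.shape
    if min(n, c, h, w) < 1:
        raise ShapeError(f"all feature-map dimensions must be >= 1, got {x.shape}")
    if divisor > 1 and c % divisor:
        raise ConfigurationError(
            f"channel count {c} must be divisible by {divisor}")


# ---------------------------------------------------------------------------
# parameter records for the functional API
# ---------------------------------------------------------------------------

@dataclass
class BatchNormState:
    """Learnable scale/shift plus running statistics of one batch-norm."""
    gamma: np.ndarray
    beta: np.ndarray
    running_mean: np.ndarray
    running_var: np.ndarray
    eps: float = 1e-5

    def apply(self, x: np.ndarray, mode: str) -> np.ndarray:
        if mode == "train":
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
        else:
            mu, var = self.running_mean, self.running_var
        sd = np.sqrt(var + self.eps)
        return ((x - mu[None, :, None, None]) / sd[None, :, None, None]
                * self.gamma[None, :, None, None] + self.beta[None, :, None, None])

    @classmethod
    def identity(cls, c: int) -> "BatchNormState":
        return cls(np.ones(c), np.zeros(c), np.zeros(c), np.ones(c))


@dataclass
class ChannelAttentionParams:
    """Position-shared MLP of the channel gate: w1 (C/4, C), w2 (C, C/4)."""
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray

    def __post_init__(self):
        c = self.w1.shape[1]
        if self.w1.shape != (c // 4, c) or self.w2.shape != (c, c // 4) \
                or self.b1.shape != (c // 4,) or self.b2.shape != (c,):
            raise ShapeError("inconsistent channel-attention parameter shapes")

    @property
    def channels(self) -> int:
        return self.w1.shape[1]


@dataclass
class SpatialAttentionParams:
    """Two 7x7 conv banks with batch-norms: conv1 (C/4, C, 7, 7), conv2 (C, C/4, 7, 7)."""
    conv1_w: np.ndarray
    conv1_b: np.ndarray
    bn1: BatchNormState
    conv2_w: np.ndarray
    conv2_b: np.ndarray
    bn2: BatchNormState

    def __post_init__(self):
        c = self.conv2_w.shape[0]
        if self.conv1_w.shape != (c // 4, c, 7, 7) or self.conv2_w.shape != (c, c // 4, 7, 7):
            raise ShapeError("inconsistent spatial-attention kernel shapes")

    @property
    def channels(self) -> int:
        return self.conv2_w.shape[0]


# ---------------------------------------------------------------------------
# functional stages
# ---------------------------------------------------------------------------

def channel_attention(x: np.ndarray, params: ChannelAttentionParams) -> np.ndarray:
    """Gate each channel vector with sigmoid(W2 relu(W1 v + b1) + b2)."""
    _check_feature_map(x)
    if x.shape[1] != params.channels:
        raise ShapeError(
            f"input has {x.shape[1]} channels but parameters expect {params.channels}")
    hidden = np.einsum("rc,nchw->nrhw", params.w1, x, optimize=True)
    hidden += params.b1[None, :, None, None]
    np.maximum(hidden, 0, out=hidden)
    logits = np.einsum("cr,nrhw->nchw", params.w2, hidden, optimize=True)
    logits += params.b2[None, :, None, None]
    return _sigmoid(logits) * x


def channel_shuffle(x: np.ndarray, groups: int = 4) -> np.ndarray:
    """Reshape the channel axis to (groups, C/groups), transpose, flatten.

    Output channel ``k * groups + i`` receives input channel
    ``i * (C / groups) + k``; values are only permuted, never altered.
    """
    _check_feature_map(x, divisor=1)
    n, c, h, w = x.shape
    if c % groups:
        raise ConfigurationError(f"channel count {c} not divisible by groups={groups}")
    cg = c // groups
    return np.ascontiguousarray(
        x.reshape(n, groups, cg, h, w).swapaxes(1, 2).reshape(n, c, h, w))


def channel_unshuffle(x: np.ndarray, groups: int = 4) -> np.ndarray:
    """Inverse permutation of :func:`channel_shuffle` with the same group count."""
    return channel_shuffle(x, groups=x.shape[1] // groups)


def spatial_attention(x: np.ndarray, params: SpatialAttentionParams,
                      mode: str = "eval") -> np.ndarray:
    """Gate with sigmoid(bn2(conv2(relu(bn1(conv1(x)))))); 7x7 convs, padding 3."""
    _check_feature_map(x)
    if mode not in ("train", "eval"):
        raise ValueError(f"mode must be 'train' or 'eval', got {mode!r}")
    if x.shape[1] != params.channels:
        raise ShapeError(
            f"input has {x.shape[1]} channels but parameters expect {params.channels}")
    h = conv2d_forward(x, params.conv1_w, params.conv1_b, padding=3)
    h = np.maximum(params.bn1.apply(h, mode), 0)
    h = conv2d_forward(h, params.conv2_w, params.conv2_b, padding=3)
    return _sigmoid(params.bn2.apply(h, mode)) * x


def gcsa_apply(x: np.ndarray, ca: ChannelAttentionParams,
               sa: SpatialAttentionParams, mode: str = "eval") -> np.ndarray:
    """channel attention -> channel shuffle -> spatial attention."""
    return spatial_attention(channel_shuffle(channel_attention(x, ca)), sa, mode=mode)


def gcsa_param_count(c: int, reduction: int = 4) -> int:
    """Learnable scalars of one GCSA instance at width ``c``.

    Counts MLP weights+biases, both 7x7 conv banks with biases, and
    batch-norm scale+shift; running statistics are not learnable.
    """
    if c % reduction:
        raise ConfigurationError(f"channel count {c} not divisible by {reduction}")
    r = c // reduction
    mlp = r * c + r + c * r + c
    spatial = (r * c * 49 + r) + 2 * r + (c * r * 49 + c) + 2 * c
    return mlp + spatial


# ---------------------------------------------------------------------------
# differentiable layer
# ---------------------------------------------------------------------------

class GCSA(nn.Module):
    """Differentiable GCSA block for one feature width ``channels``.

    ``reduction`` (bottleneck ratio of both gates) and ``groups`` (shuffle
    group count) default to 4.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 4, groups: int = 4):
        super().__init__()
        if channels % reduction or channels % groups:
            raise ConfigurationError(
                f"channels={channels} must be divisible by reduction={reduction} "
                f"and groups={groups}")
        self.channels = channels
        self.groups = groups
        hidden = channels // reduction
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, channels, rng)
        self.conv1 = nn.Conv2d(channels, hidden, 7, rng, padding=3, init="trunc_normal")
        self.bn1 = nn.BatchNorm2d(hidden)
        self.conv2 = nn.Conv2d(hidden, channels, 7, rng, padding=3, init="trunc_normal")
        self.bn2 = nn.BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.channels:
            raise ShapeError(f"expected {self.channels} channels, got {c}")
        # channel gate, MLP shared across positions
        t = x.transpose(0, 2, 3, 1)
        gate = self.fc2(self.fc1(t).relu()).sigmoid().transpose(0, 3, 1, 2)
        x = x * gate
        # shuffle
        cg = c // self.groups
        x = x.reshape(n, self.groups, cg, h, w).transpose(0, 2, 1, 3, 4).reshape(n, c, h, w)
        # spatial gate
        g = self.bn2(self.conv2(self.bn1(self.conv1(x)).relu())).sigmoid()
        return x * g

    def export_params(self) -> tuple[ChannelAttentionParams, SpatialAttentionParams]:
        """Snapshot as functional-API parameter records (weights transposed to
        the (out, in) convention of :class:`ChannelAttentionParams`)."""
        ca = ChannelAttentionParams(
            w1=self.fc1.weight.data.T.copy(), b1=self.fc1.bias.data.copy(),
            w2=self.fc2.weight.data.T.copy(), b2=self.fc2.bias.data.copy())
        sa = SpatialAttentionParams(
            conv1_w=self.conv1.weight.data.copy(), conv1_b=self.conv1.bias.data.copy(),
            bn1=BatchNormState(self.bn1.gamma.data.copy(), self.bn1.beta.data.copy(),
                               self.bn1.running_mean.copy(), self.bn1.running_var.copy(),
                               self.bn1.eps),
            conv2_w=self.conv2.weight.data.copy(), conv2_b=self.conv2.bias.data.copy(),
            bn2=BatchNormState(self.bn2.gamma.data.copy(), self.bn2.beta.data.copy(),
                               self.bn2.running_mean.copy(), self.bn2.running_var.copy(),
                               self.bn2.eps))
        return ca, sa


def init_channel_attention_params(c: int, rng: np.random.Generator) -> ChannelAttentionParams:
    r = c // 4
    return ChannelAttentionParams(
        w1=nn.trunc_normal_(rng, (r, c)), b1=np.zeros(r, dtype=np.float32),
        w2=nn.trunc_normal_(rng, (c, r)), b2=np.zeros(c, dtype=np.float32))


def init_spatial_attention_params(c: int, rng: np.random.Generator) -> SpatialAttentionParams:
    r = c // 4
    return SpatialAttentionParams(
        conv1_w=nn.trunc_normal_(rng, (r, c, 7, 7)), conv1_b=np.zeros(r, dtype=np.float32),
        bn1=BatchNormState.identity(r),
        conv2_w=nn.trunc_normal_(rng, (c, r, 7, 7)), conv2_b=np.zeros(c, dtype=np.float32),
        bn2=BatchNormState.identity(c))
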
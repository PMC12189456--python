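"""GCSA-SegFormer network: MiT-B0-style encoder, GCSA bottleneck, all-MLP decoder.

The encoder is a four-stage hierarchical Mix Transformer.  Each stage embeds
patches with an overlapped strided convolution and runs Transformer blocks
whose self-attention reduces the key/value sequence with a strided
convolution (spatial-reduction ratios 8/4/2/1) and whose feed-forward adds a
3x3 depthwise convolution (Mix-FFN).  Stages output feature maps at strides
4/8/16/32 with the configured widths.

When enabled, one independent GCSA block per stage refines each encoder
output at the encoder-decoder junction.  The decoder projects every stage to
a common width, bilinearly upsamples to stride 4, concatenates (4x width),
fuses with a linear layer, and classifies per pixel; the final logits are
upsampled back to the input resolution.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import nn
from .attention import GCSA
from .exceptions import ConfigurationError, ShapeError
from .nn.functional import bilinear_resize, softmax
from .nn.tensor import Tensor, concat, no_grad

_STRIDES = (4, 8, 16, 32)
_EMBED_KERNELS = (7, 3, 3, 3)
_EMBED_STRIDES = (4, 2, 2, 2)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults follow the MiT-B0 recipe)."""
    num_classes: int = 2
    stage_channels: tuple[int, ...] = (32, 64, 160, 256)
    stage_depths: tuple[int, ...] = (2, 2, 2, 2)
    stage_heads: tuple[int, ...] = (1, 2, 5, 8)
    sr_ratios: tuple[int, ...] = (8, 4, 2, 1)
    decoder_dim: int = 256
    gcsa_enabled: bool = True
    patch_size: int = 512
    mlp_ratio: int = 4
    drop_rate: float = 0.0
    gcsa_reduction: int = 4
    gcsa_groups: int = 4

    def __post_init__(self):
        for name in ("stage_channels", "stage_depths", "stage_heads", "sr_ratios"):
            val = tuple(getattr(self, name))
            object.__setattr__(self, name, val)
            if len(val) != 4:
                raise ConfigurationError(f"{name} must have 4 entries, got {val}")
        if self.num_classes < 2:
            raise ConfigurationError("num_classes must be >= 2")
        for c, h in zip(self.stage_channels, self.stage_heads):
            if c % h:
                raise ConfigurationError(f"stage width {c} not divisible by {h} heads")
            if self.gcsa_enabled and c % self.gcsa_reduction:
                raise ConfigurationError(
                    f"stage width {c} must be divisible by {self.gcsa_reduction} "
                    "when the GCSA bottleneck is enabled")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: (tuple(v) if isinstance(v, list) else v)
                      for k, v in d.items() if k in known})


# ---------------------------------------------------------------------------
# encoder pieces
# ---------------------------------------------------------------------------

class OverlapPatchEmbed(nn.Module):
    def __init__(self, in_ch, out_ch, kernel, stride, rng):
        super().__init__()
        self.proj = nn.Conv2d(in_ch, out_ch, kernel, rng, stride=stride,
                              padding=kernel // 2)
        self.norm = nn.LayerNorm(out_ch)

    def forward(self, x: Tensor) -> tuple[Tensor, int, int]:
        x = self.proj(x)
        n, c, h, w = x.shape
        tokens = x.reshape(n, c, h * w).transpose(0, 2, 1)
        return self.norm(tokens), h, w


class EfficientSelfAttention(nn.Module):
    """Multi-head self-attention with strided-conv key/value reduction."""

    def __init__(self, dim, heads, sr_ratio, rng):
        super().__init__()
        self.heads = heads
        self.head_dim = dim // heads
        self.scale = self.head_dim ** -0.5
        self.sr_ratio = sr_ratio
        self.q = nn.Linear(dim, dim, rng)
        self.kv = nn.Linear(dim, 2 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        if sr_ratio > 1:
            self.sr = nn.Conv2d(dim, dim, sr_ratio, rng, stride=sr_ratio)
            self.sr_norm = nn.LayerNorm(dim)

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        n, L, c = x.shape
        q = self.q(x).reshape(n, L, self.heads, self.head_dim).transpose(0, 2, 1, 3)
        if self.sr_ratio > 1:
            xr = x.transpose(0, 2, 1).reshape(n, c, h, w)
            xr = self.sr(xr)
            lr = xr.shape[2] * xr.shape[3]
            xr = xr.reshape(n, c, lr).transpose(0, 2, 1)
            xr = self.sr_norm(xr)
        else:
            xr, lr = x, L
        kv = self.kv(xr).reshape(n, lr, 2, self.heads, self.head_dim)
        kv = kv.transpose(2, 0, 3, 1, 4)
        k, v = kv[0], kv[1]
        attn = softmax((q @ k.transpose(0, 1, 3, 2)) * self.scale, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, L, c)
        return self.proj(out)


class MixFFN(nn.Module):
    """Feed-forward with a 3x3 depthwise convolution between the two linears."""

    def __init__(self, dim, hidden, rng):
        super().__init__()
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.dwconv = nn.Conv2d(hidden, hidden, 3, rng, padding=1, groups=hidden)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        n, L, _ = x.shape
        t = self.fc1(x)
        hid = t.shape[-1]
        t = t.transpose(0, 2, 1).reshape(n, hid, h, w)
        t = self.dwconv(t)
        t = t.reshape(n, hid, L).transpose(0, 2, 1)
        return self.fc2(t.gelu())


class TransformerBlock(nn.Module):
    def __init__(self, dim, heads, sr_ratio, mlp_ratio, rng):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.attn = EfficientSelfAttention(dim, heads, sr_ratio, rng)
        self.norm2 = nn.LayerNorm(dim)
        self.ffn = MixFFN(dim, dim * mlp_ratio, rng)

    def forward(self, x: Tensor, h: int, w: int) -> Tensor:
        x = x + self.attn(self.norm1(x), h, w)
        return x + self.ffn(self.norm2(x), h, w)


class EncoderStage(nn.Module):
    def __init__(self, in_ch, out_ch, kernel, stride, depth, heads, sr_ratio,
                 mlp_ratio, rng):
        super().__init__()
        self.embed = OverlapPatchEmbed(in_ch, out_ch, kernel, stride, rng)
        self.blocks = [TransformerBlock(out_ch, heads, sr_ratio, mlp_ratio, rng)
                       for _ in range(depth)]
        self.norm = nn.LayerNorm(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        tokens, h, w = self.embed(x)
        for blk in self.blocks:
            tokens = blk(tokens, h, w)
        tokens = self.norm(tokens)
        n, _, c = tokens.shape
        return tokens.transpose(0, 2, 1).reshape(n, c, h, w)


class MixTransformerEncoder(nn.Module):
    def __init__(self, config: ModelConfig, rng):
        super().__init__()
        stages = []
        in_ch = 3
        for i in range(4):
            stages.append(EncoderStage(
                in_ch, config.stage_channels[i], _EMBED_KERNELS[i],
                _EMBED_STRIDES[i], config.stage_depths[i], config.stage_heads[i],
                config.sr_ratios[i], config.mlp_ratio, rng))
            in_ch = config.stage_channels[i]
        self.stages = stages

    def forward(self, x: Tensor) -> list[Tensor]:
        feats = []
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return feats


class AllMLPDecoder(nn.Module):
    """Project every stage to ``dim``, upsample to stride 4, fuse, classify.

    Fusion is a 1x1 convolution with batch-norm and ReLU, as in the
    reference all-MLP head.
    """

    def __init__(self, config: ModelConfig, rng):
        super().__init__()
        self.proj = [nn.Linear(c, config.decoder_dim, rng)
                     for c in config.stage_channels]
        self.fuse = nn.Conv2d(4 * config.decoder_dim, config.decoder_dim, 1, rng,
                              bias=False)
        self.fuse_bn = nn.BatchNorm2d(config.decoder_dim)
        self.classifier = nn.Conv2d(config.decoder_dim, config.num_classes, 1, rng)

    def forward(self, feats: list[Tensor]) -> Tensor:
        th, tw = feats[0].shape[2], feats[0].shape[3]
        maps = []
        for f, proj in zip(feats, self.proj):
            n, c, h, w = f.shape
            t = proj(f.transpose(0, 2, 3, 1)).transpose(0, 3, 1, 2)
            maps.append(bilinear_resize(t, th, tw))
        x = concat(maps, axis=1)
        x = self.fuse_bn(self.fuse(x)).relu()
        return self.classifier(x)


class GCSASegFormerNet(nn.Module):
    """End-to-end differentiable network (encoder -> GCSA -> decoder)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.encoder = MixTransformerEncoder(config, rng)
        if config.gcsa_enabled:
            self.gcsa = [GCSA(c, rng, reduction=config.gcsa_reduction,
                              groups=config.gcsa_groups)
                         for c in config.stage_channels]
        else:
            self.gcsa = []
        self.decoder = AllMLPDecoder(config, rng)

    def encode(self, x: Tensor) -> list[Tensor]:
        _check_image(x.data if isinstance(x, Tensor) else x)
        return self.encoder(x)

    def refine(self, feats: list[Tensor]) -> list[Tensor]:
        if not self.config.gcsa_enabled:
            return feats
        return [blk(f) for blk, f in zip(self.gcsa, feats)]

    def decode(self, feats: list[Tensor]) -> Tensor:
        shapes = [f.shape for f in feats]
        for i in range(4):
            if shapes[i][2] * _STRIDES[i] != shapes[0][2] * _STRIDES[0] or \
               shapes[i][3] * _STRIDES[i] != shapes[0][3] * _STRIDES[0]:
                raise ShapeError(f"inconsistent stage shapes: {shapes}")
        return self.decoder(feats)

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        logits = self.decode(self.refine(self.encode(x)))
        return bilinear_resize(logits, h, w)


def _check_image(x: np.ndarray) -> None:
    if x.ndim != 4 or x.shape[1] != 3:
        raise ShapeError(f"expected an (N, 3, H, W) image batch, got shape {x.shape}")
    h, w = x.shape[2], x.shape[3]
    if h % 32 or w % 32:
        raise ShapeError(
            f"input height and width must be divisible by 32 (the product of the "
            f"four stage strides); got {h}x{w}")


# ---------------------------------------------------------------------------
# operation-level API (plain arrays in and out)
# ---------------------------------------------------------------------------

def build_model(config: ModelConfig, seed: int = 0) -> GCSASegFormerNet:
    """Construct a network with deterministic initialization under ``seed``."""
    return GCSASegFormerNet(config, seed=seed)


def encode(image: np.ndarray, model: GCSASegFormerNet) -> list[np.ndarray]:
    """Run the hierarchical encoder; returns four stage maps (strides 4/8/16/32)."""
    _check_image(np.asarray(image))
    model.eval()
    with no_grad():
        feats = model.encode(Tensor(np.asarray(image, dtype=np.float32)))
    return [f.data for f in feats]


def apply_gcsa(features: list[np.ndarray], model: GCSASegFormerNet) -> list[np.ndarray]:
    """Pass each stage map through its GCSA block (identity when disabled)."""
    model.eval()
    with no_grad():
        out = model.refine([Tensor(np.asarray(f, dtype=np.float32)) for f in features])
    return [f.data for f in out]


def decode(features: list[np.ndarray], model: GCSASegFormerNet) -> np.ndarray:
    """All-MLP decoder; returns logits at stride 4: (N, num_classes, H/4, W/4)."""
    model.eval()
    with no_grad():
        out = model.decode([Tensor(np.asarray(f, dtype=np.float32)) for f in features])
    return out.data


def forward(image: np.ndarray, model: GCSASegFormerNet, mode: str = "eval") -> np.ndarray:
    """Full network pass; logits at input resolution (N, num_classes, H, W)."""
    if mode == "train":
        model.train()
        out = model(Tensor(np.asarray(image, dtype=np.float32)))
        return out.data
    model.eval()
    with no_grad():
        out = model(Tensor(np.asarray(image, dtype=np.float32)))
    return out.data
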
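"""Synthetic histology-like fixtures: textured RGB patches with blob masks.

Real HE-stained tissue is unavailable offline, so tests and examples run on
generated patches: an eosin-like pink noise background with a union of
hematoxylin-like purple ellipses as the "tumor" foreground, plus the exact
{0, 255} mask.  The two textures' mean colors are separated enough that the
segmentation task is learnable by a small network; geometry, texture and
randomness are fully controlled by :class:`SynthSpec` and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.draw import ellipse as _ellipse

from .tiling import split_dataset, SplitManifest


@dataclass(frozen=True)
class TextureSpec:
    """Gaussian color-noise texture: per-channel mean and shared std (8-bit)."""
    mean: tuple[float, float, float]
    std: float = 12.0


@dataclass(frozen=True)
class SynthSpec:
    seed: int = 0
    width: int = 512
    height: int = 512
    n_blobs: int = 3
    blob_radius_range: tuple[float, float] = (40.0, 120.0)
    foreground_texture: TextureSpec = TextureSpec((120.0, 70.0, 155.0))   # hematoxylin-ish
    background_texture: TextureSpec = TextureSpec((231.0, 180.0, 197.0))  # eosin-ish
    min_color_margin: float = 30.0

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ValueError("width and height must be >= 1")
        lo, hi = self.blob_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("blob radii must be positive and ordered")
        if self.n_blobs > 0 and hi >= min(self.width, self.height):
            raise ValueError(
                f"blob radius {hi} does not fit in a {self.width}x{self.height} image")
        sep = np.linalg.norm(np.subtract(self.foreground_texture.mean,
                                         self.background_texture.mean))
        if self.n_blobs > 0 and sep < self.min_color_margin:
            raise ValueError(
                f"texture means separated by {sep:.1f} < margin {self.min_color_margin}; "
                "the task would not be learnable")


def _texture(rng: np.random.Generator, shape_hw: tuple[int, int],
             tex: TextureSpec) -> np.ndarray:
    noise = rng.normal(0.0, tex.std, size=shape_hw + (3,))
    return np.clip(np.asarray(tex.mean) + noise, 0, 255)


def make_patch(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray]:
    """Render one (RGB uint8 image, {0,255} uint8 mask) pair, seed-deterministic.

    Ellipse centers are kept a maximal radius away from the border whenever
    the image is large enough, so blobs are usually unclipped.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    image = _texture(rng, (h, w), spec.background_texture)
    mask = np.zeros((h, w), dtype=np.uint8)
    lo, hi = spec.blob_radius_range
    for _ in range(spec.n_blobs):
        ra = rng.uniform(lo, hi)
        rb = rng.uniform(lo, hi)
        rot = rng.uniform(0, math.pi)
        cy = rng.uniform(hi, h - hi) if h > 2 * hi else rng.uniform(0, h)
        cx = rng.uniform(hi, w - hi) if w > 2 * hi else rng.uniform(0, w)
        rr, cc = _ellipse(cy, cx, ra, rb, shape=(h, w), rotation=rot)
        mask[rr, cc] = 255
    fg = _texture(rng, (h, w), spec.foreground_texture)
    sel = mask == 255
    image[sel] = fg[sel]
    return image.astype(np.uint8), mask


def make_wsi(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray]:
    """A slide-sized patch pair; same renderer, intended for multi-tile grids."""
    return make_patch(spec)


def make_dataset(spec: SynthSpec, n: int, out_dir: str | Path,
                 ) -> tuple[Path, SplitManifest]:
    """Write ``n`` seeded pairs as ``images/<id>.png`` + ``masks/<id>.png``
    with a 7:2:1 ``split.txt``; byte-identical on regeneration."""
    if n < 10:
        raise ValueError("a dataset needs at least 10 patches for a 7:2:1 split")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    ids = []
    children = np.random.SeedSequence(spec.seed).spawn(n)
    for i, ss in enumerate(children):
        pid = f"patch_{i:05d}"
        ids.append(pid)
        sub = SynthSpec(**{**spec.__dict__, "seed": int(ss.generate_state(1)[0] % (2 ** 31))})
        image, mask = make_patch(sub)
        Image.fromarray(image).save(out / "images" / f"{pid}.png")
        Image.fromarray(mask).save(out / "masks" / f"{pid}.png")
    manifest = split_dataset(ids, seed=spec.seed)
    (out / "split.txt").write_text(manifest.to_text())
    return out, manifest


def load_pairs(data_dir: str | Path, ids: list[str] | None = None,
               ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Read (image, mask) pairs from the :func:`make_dataset` layout."""
    data_dir = Path(data_dir)
    if ids is None:
        ids = sorted(p.stem for p in (data_dir / "images").glob("*.png"))
    pairs = []
    for pid in ids:
        image = np.asarray(Image.open(data_dir / "images" / f"{pid}.png").convert("RGB"))
        mask = np.asarray(Image.open(data_dir / "masks" / f"{pid}.png").convert("L"))
        pairs.append((image, mask))
    return pairs


def make_memory_dataset(spec: SynthSpec, n: int
                        ) -> tuple[list[tuple[np.ndarray, np.ndarray]], SplitManifest]:
    """As :func:`make_dataset` but kept in memory (no files written)."""
    children = np.random.SeedSequence(spec.seed).spawn(n)
    pairs = []
    ids = []
    for i, ss in enumerate(children):
        ids.append(f"patch_{i:05d}")
        sub = SynthSpec(**{**spec.__dict__, "seed": int(ss.generate_state(1)[0] % (2 ** 31))})
        pairs.append(make_patch(sub))
    manifest = split_dataset(ids, seed=spec.seed)
    return pairs, manifest
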
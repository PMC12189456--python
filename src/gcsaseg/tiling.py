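"""Whole-slide-image tiling, stitching, label harmonization and splitting.

Gigapixel slides cannot be fed to the network directly, so a slide is cut on
a fixed non-overlapping 512x512 lattice (zero-padded on the right/bottom
edges to the next multiple), each tile is segmented independently, and the
predicted tiles are reassembled and cropped back to the original size.
Multi-class pathology annotations are collapsed to binary {0, 255} masks
(255 = tumor foreground) before training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, ShapeError

PATCH_SIZE = 512

#: annotation class -> binary mask value, per dataset labelling scheme.
#: liver: hepatocellular carcinoma and microvascular invasion form the tumor
#: foreground; breast (bach): in-situ plus invasive carcinoma do.
SCHEMES: dict[str, dict[str, int]] = {
    "liver": {"roi": 0, "non-roi": 0, "hcc": 255, "mvi": 255},
    "bach": {"normal": 0, "benign": 0, "in-situ": 255, "invasive": 255},
}


@dataclass(frozen=True)
class TileGrid:
    """Geometry linking a large image to its row-major patch lattice."""
    orig_w: int
    orig_h: int
    patch: int = PATCH_SIZE
    rows: int = field(init=False)
    cols: int = field(init=False)
    pad_right: int = field(init=False)
    pad_bottom: int = field(init=False)

    def __post_init__(self):
        if self.patch < 1:
            raise ConfigurationError("patch size must be >= 1")
        if self.orig_w < 1 or self.orig_h < 1:
            raise ShapeError("image dimensions must be >= 1")
        object.__setattr__(self, "rows", math.ceil(self.orig_h / self.patch))
        object.__setattr__(self, "cols", math.ceil(self.orig_w / self.patch))
        object.__setattr__(self, "pad_right", self.cols * self.patch - self.orig_w)
        object.__setattr__(self, "pad_bottom", self.rows * self.patch - self.orig_h)

    @property
    def n_patches(self) -> int:
        return self.rows * self.cols

    def to_text(self) -> str:
        return "".join(f"{k} {getattr(self, k)}\n" for k in
                       ("orig_w", "orig_h", "patch", "rows", "cols",
                        "pad_right", "pad_bottom"))

    @classmethod
    def from_text(cls, text: str) -> "TileGrid":
        kv = dict(line.split() for line in text.strip().splitlines())
        return cls(orig_w=int(kv["orig_w"]), orig_h=int(kv["orig_h"]),
                   patch=int(kv["patch"]))


@dataclass(frozen=True)
class SplitManifest:
    """Deterministic 7:2:1 partition of patch identifiers."""
    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]
    seed: int
    ratio: tuple[int, int, int] = (7, 2, 1)

    def to_text(self) -> str:
        lines = [f"seed {self.seed}", f"ratio {self.ratio[0]}:{self.ratio[1]}:{self.ratio[2]}"]
        for name in ("train", "val", "test"):
            for pid in getattr(self, name):
                lines.append(f"{name} {pid}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "SplitManifest":
        seed = 0
        ratio = (7, 2, 1)
        buckets: dict[str, list[str]] = {"train": [], "val": [], "test": []}
        for line in text.strip().splitlines():
            key, val = line.split(None, 1)
            if key == "seed":
                seed = int(val)
            elif key == "ratio":
                ratio = tuple(int(v) for v in val.split(":"))
            else:
                buckets[key].append(val)
        return cls(tuple(buckets["train"]), tuple(buckets["val"]),
                   tuple(buckets["test"]), seed=seed, ratio=ratio)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def harmonize_labels(annotation: np.ndarray, scheme: str,
                     names: dict[int, str] | None = None) -> np.ndarray:
    """Collapse a per-pixel class map to a binary {0, 255} uint8 mask.

    ``annotation`` is a 2-D array of class names (string dtype) or, with
    ``names`` mapping codes to class names, of integer codes.  Class names
    are matched case-insensitively with ``_``/``-`` treated alike.
    """
    if scheme not in SCHEMES:
        raise ConfigurationError(f"unknown scheme {scheme!r}; choose from {sorted(SCHEMES)}")
    table = SCHEMES[scheme]
    annotation = np.asarray(annotation)
    if annotation.ndim != 2:
        raise ShapeError(f"annotation must be 2-D, got ndim={annotation.ndim}")
    if annotation.size == 0:
        return np.zeros(annotation.shape, dtype=np.uint8)

    def canon(label) -> str:
        return str(label).strip().lower().replace("_", "-").replace(" ", "-")

    if annotation.dtype.kind in "iu":
        if names is None:
            raise ConfigurationError("integer annotations require a code->name mapping")
        lut = {code: canon(name) for code, name in names.items()}
        labels, inverse = np.unique(annotation, return_inverse=True)
        resolved = []
        for code in labels:
            if int(code) not in lut:
                raise ValueError(f"unknown annotation code {int(code)}")
            resolved.append(lut[int(code)])
    else:
        labels, inverse = np.unique(annotation, return_inverse=True)
        resolved = [canon(l) for l in labels]
    values = []
    for label in resolved:
        if label not in table:
            raise ValueError(f"unknown class label {label!r} for scheme {scheme!r}")
        values.append(table[label])
    return np.asarray(values, dtype=np.uint8)[inverse].reshape(annotation.shape)


def tile_image(image: np.ndarray, patch: int = PATCH_SIZE) -> tuple[list[np.ndarray], TileGrid]:
    """Cut an image into non-overlapping ``patch`` x ``patch`` tiles, row-major.

    The image is zero-padded on the right and bottom to the next multiple of
    ``patch``; works for 2-D masks and (H, W, C) color images alike.
    """
    image = np.asarray(image)
    if image.ndim not in (2, 3):
        raise ShapeError(f"expected a 2-D mask or (H, W, C) image, got ndim={image.ndim}")
    h, w = image.shape[:2]
    grid = TileGrid(orig_w=w, orig_h=h, patch=patch)
    pad = [(0, grid.pad_bottom), (0, grid.pad_right)] + [(0, 0)] * (image.ndim - 2)
    padded = np.pad(image, pad)
    patches = []
    for r in range(grid.rows):
        for c in range(grid.cols):
            patches.append(padded[r * patch:(r + 1) * patch,
                                  c * patch:(c + 1) * patch].copy())
    return patches, grid


def stitch(patches: list[np.ndarray], grid: TileGrid) -> np.ndarray:
    """Reassemble row-major tiles and crop to the original size.

    Exact inverse of :func:`tile_image`.
    """
    if len(patches) != grid.n_patches:
        raise ShapeError(f"expected {grid.n_patches} patches, got {len(patches)}")
    first = np.asarray(patches[0])
    p = grid.patch
    for q in patches:
        if np.asarray(q).shape[:2] != (p, p):
            raise ShapeError(f"every patch must be {p}x{p}, got {np.asarray(q).shape[:2]}")
    extra = first.shape[2:]
    full = np.zeros((grid.rows * p, grid.cols * p) + extra, dtype=first.dtype)
    for i, q in enumerate(patches):
        r, c = divmod(i, grid.cols)
        full[r * p:(r + 1) * p, c * p:(c + 1) * p] = q
    return full[:grid.orig_h, :grid.orig_w]


def split_dataset(ids: list[str], seed: int,
                  ratio: tuple[int, int, int] = (7, 2, 1)) -> SplitManifest:
    """Deterministic shuffle then 7:2:1 cut (floor rule, remainder to test)."""
    ids = [str(i) for i in ids]
    if not ids:
        raise ValueError("ids must be non-empty")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in split input")
    order = list(ids)
    np.random.default_rng(seed).shuffle(order)
    n = len(order)
    total = sum(ratio)
    n_train = int(n * ratio[0] / total)
    n_val = int(n * ratio[1] / total)
    return SplitManifest(train=tuple(order[:n_train]),
                         val=tuple(order[n_train:n_train + n_val]),
                         test=tuple(order[n_train + n_val:]),
                         seed=seed, ratio=ratio)
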
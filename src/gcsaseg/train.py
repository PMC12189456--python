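"""Training, patch prediction, and whole-slide inference.

The training recipe follows the published regime: AdamW (first-moment
coefficient 0.9, weight decay 0.02), learning rate 1e-4 with step decay,
pixelwise cross-entropy on two classes, batch size 8, 50 epochs, one fixed
seed governing initialization and data order.  The best-validation-MIoU
parameter state is returned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import ShapeError
from .metrics import evaluate_set
from .model import GCSASegFormerNet, ModelConfig, build_model
from .nn.functional import softmax_cross_entropy
from .nn.optim import AdamW, StepLR
from .nn.tensor import Tensor, no_grad
from .tiling import stitch, tile_image


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    weight_decay: float = 0.02
    epochs: int = 50
    batch: int = 8
    seed: int = 0
    lr_step: int = 20       # epochs between step decays
    lr_factor: float = 0.1  # multiplicative decay per step

    def __post_init__(self):
        if self.epochs < 1 or self.batch < 1:
            raise ValueError("epochs and batch must be >= 1")
        if self.lr < 0:
            raise ValueError("learning rate must be >= 0")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class TrainHistory:
    """One record per completed epoch."""
    train_loss: list[float] = field(default_factory=list)
    val_miou: list[float] = field(default_factory=list)
    val_mpa: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["epoch\ttrain_loss\tval_miou\tval_mpa\tval_accuracy\tlr"]
        for i in range(len(self.train_loss)):
            lines.append(f"{i + 1}\t{self.train_loss[i]:.6f}\t{self.val_miou[i]:.6f}"
                         f"\t{self.val_mpa[i]:.6f}\t{self.val_accuracy[i]:.6f}"
                         f"\t{self.lr[i]:.8g}")
        return "\n".join(lines) + "\n"


def _validate_pairs(pairs, name: str) -> None:
    for i, (image, mask) in enumerate(pairs):
        image, mask = np.asarray(image), np.asarray(mask)
        if image.shape[:2] != mask.shape:
            raise ShapeError(f"{name}[{i}]: image {image.shape[:2]} vs mask {mask.shape}")
        if not np.isin(mask, (0, 255)).all():
            raise ValueError(f"{name}[{i}]: mask contains values outside {{0, 255}}")


def _to_batch(pairs) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([np.asarray(im, dtype=np.float32).transpose(2, 0, 1) / 255.0
                  for im, _ in pairs])
    y = np.stack([(np.asarray(m) == 255).astype(np.int64) for _, m in pairs])
    return x, y


def train(model: GCSASegFormerNet, train_set, val_set,
          config: TrainConfig) -> tuple[GCSASegFormerNet, TrainHistory]:
    """Optimize ``model`` on (image, mask) pairs; returns best-val-MIoU state.

    Deterministic given ``config.seed``: initialization is the model's,
    per-epoch shuffling derives from (seed, epoch), and there are no other
    stochastic layers at the default drop rate.
    """
    if not train_set:
        raise ValueError("training set is empty")
    _validate_pairs(train_set, "train")
    _validate_pairs(val_set, "val")
    x_train, y_train = _to_batch(train_set)
    optimizer = AdamW(model.parameters(), lr=config.lr,
                      betas=(config.beta1, config.beta2),
                      weight_decay=config.weight_decay)
    scheduler = StepLR(optimizer, step_size=config.lr_step, factor=config.lr_factor)
    history = TrainHistory()
    best_miou = -1.0
    best_state = model.state_dict()
    n = len(train_set)
    for epoch in range(config.epochs):
        model.train()
        order = np.arange(n)
        np.random.default_rng([config.seed, epoch]).shuffle(order)
        losses = []
        lr_used = optimizer.lr
        for start in range(0, n, config.batch):
            idx = order[start:start + config.batch]
            optimizer.zero_grad()
            logits = model(Tensor(x_train[idx]))
            loss = softmax_cross_entropy(logits, y_train[idx])
            loss.backward()
            optimizer.step()
            losses.append(loss.item())
        scheduler.step()
        if val_set:
            preds = [(predict_patch(model, im), m) for im, m in val_set]
            vm, vp, va = evaluate_set(preds, aggregate="micro")
        else:
            vm = vp = va = float("nan")
        history.train_loss.append(float(np.mean(losses)))
        history.val_miou.append(vm)
        history.val_mpa.append(vp)
        history.val_accuracy.append(va)
        history.lr.append(lr_used)
        if val_set and vm > best_miou:
            best_miou = vm
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return model, history


def predict_patch(model: GCSASegFormerNet, image: np.ndarray) -> np.ndarray:
    """Segment one RGB patch; returns a {0, 255} uint8 mask, argmax over classes."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ShapeError(f"expected an (H, W, 3) patch, got shape {image.shape}")
    x = image.astype(np.float32).transpose(2, 0, 1)[None] / 255.0
    model.eval()
    with no_grad():
        logits = model(Tensor(x)).data[0]
    return (np.argmax(logits, axis=0) * 255).astype(np.uint8)


def predict_wsi(model: GCSASegFormerNet, image: np.ndarray,
                patch: int | None = None) -> np.ndarray:
    """Tile a large image, segment each tile, stitch predictions back.

    Output mask has exactly the input's spatial size.
    """
    patch = patch or model.config.patch_size
    patches, grid = tile_image(np.asarray(image), patch=patch)
    preds = [predict_patch(model, p) for p in patches]
    return stitch(preds, grid)


# ---------------------------------------------------------------------------
# checkpoints: flat name -> array mapping plus the build config
# ---------------------------------------------------------------------------

def save_checkpoint(model: GCSASegFormerNet, path: str | Path) -> None:
    state = model.state_dict()
    meta = np.frombuffer(json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, __model_config__=meta, **state)


def load_checkpoint(path: str | Path) -> GCSASegFormerNet:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__model_config__"]).decode())
        state = {k: archive[k] for k in archive.files if k != "__model_config__"}
    model = build_model(ModelConfig.from_dict(meta), seed=0)
    model.load_state_dict(state)
    return model
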
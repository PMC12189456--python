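"""Scikit-learn style estimator facade over the segmentation pipeline.

``GCSASegFormer`` is a fit/predict wrapper compatible with sklearn's
``get_params``/``set_params``/``clone`` machinery, so it composes with model
selection utilities.  ``X`` is an (N, H, W, 3) uint8 image stack and ``y``
an (N, H, W) {0, 255} mask stack; ``predict`` returns masks of the same
form and ``score`` the mean intersection-over-union on pooled pixels.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .metrics import evaluate_set
from .model import ModelConfig, build_model
from .train import TrainConfig, predict_patch, predict_wsi, train


class GCSASegFormer(BaseEstimator):
    """Hierarchical-Transformer tumor segmenter with a GCSA bottleneck.

    Parameters mirror :class:`~gcsaseg.model.ModelConfig` and
    :class:`~gcsaseg.train.TrainConfig`; fitted state lives in ``model_``
    and ``history_``.
    """

    def __init__(self, num_classes: int = 2,
                 stage_channels: tuple[int, ...] = (32, 64, 160, 256),
                 stage_depths: tuple[int, ...] = (2, 2, 2, 2),
                 stage_heads: tuple[int, ...] = (1, 2, 5, 8),
                 sr_ratios: tuple[int, ...] = (8, 4, 2, 1),
                 decoder_dim: int = 256, gcsa_enabled: bool = True,
                 patch_size: int = 512, lr: float = 1e-4,
                 weight_decay: float = 0.02, epochs: int = 50, batch: int = 8,
                 lr_step: int = 20, lr_factor: float = 0.1,
                 val_fraction: float = 0.2, random_state: int = 0):
        self.num_classes = num_classes
        self.stage_channels = stage_channels
        self.stage_depths = stage_depths
        self.stage_heads = stage_heads
        self.sr_ratios = sr_ratios
        self.decoder_dim = decoder_dim
        self.gcsa_enabled = gcsa_enabled
        self.patch_size = patch_size
        self.lr = lr
        self.weight_decay = weight_decay
        self.epochs = epochs
        self.batch = batch
        self.lr_step = lr_step
        self.lr_factor = lr_factor
        self.val_fraction = val_fraction
        self.random_state = random_state

    # -- config assembly --------------------------------------------------
    def _model_config(self) -> ModelConfig:
        return ModelConfig(num_classes=self.num_classes,
                           stage_channels=tuple(self.stage_channels),
                           stage_depths=tuple(self.stage_depths),
                           stage_heads=tuple(self.stage_heads),
                           sr_ratios=tuple(self.sr_ratios),
                           decoder_dim=self.decoder_dim,
                           gcsa_enabled=self.gcsa_enabled,
                           patch_size=self.patch_size)

    def _train_config(self) -> TrainConfig:
        return TrainConfig(lr=self.lr, weight_decay=self.weight_decay,
                           epochs=self.epochs, batch=self.batch,
                           seed=self.random_state, lr_step=self.lr_step,
                           lr_factor=self.lr_factor)

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y) -> "GCSASegFormer":
        X = np.asarray(X)
        y = np.asarray(y)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError(f"X must be (N, H, W, 3), got {X.shape}")
        if y.shape != X.shape[:3]:
            raise ValueError(f"y must be (N, H, W) matching X, got {y.shape}")
        pairs = [(X[i], y[i]) for i in range(len(X))]
        if self.val_fraction > 0 and len(pairs) >= 2:
            n_val = max(1, int(round(self.val_fraction * len(pairs))))
            order = np.random.default_rng(self.random_state).permutation(len(pairs))
            val_idx = set(order[:n_val].tolist())
            train_pairs = [pairs[i] for i in range(len(pairs)) if i not in val_idx]
            val_pairs = [pairs[i] for i in sorted(val_idx)]
        else:
            train_pairs, val_pairs = pairs, []
        model = build_model(self._model_config(), seed=self.random_state)
        self.model_, self.history_ = train(model, train_pairs, val_pairs,
                                           self._train_config())
        self.n_features_in_ = int(np.prod(X.shape[1:]))
        return self

    def predict(self, X) -> np.ndarray:
        self._check_fitted()
        X = np.asarray(X)
        return np.stack([predict_patch(self.model_, X[i]) for i in range(len(X))])

    def predict_slide(self, image: np.ndarray) -> np.ndarray:
        """Segment one arbitrarily sized slide by tiling and stitching."""
        self._check_fitted()
        return predict_wsi(self.model_, image)

    def score(self, X, y) -> float:
        """Pooled-pixel MIoU of predictions against {0,255} truth masks."""
        preds = self.predict(X)
        y = np.asarray(y)
        m, _, _ = evaluate_set([(preds[i], y[i]) for i in range(len(preds))])
        return m

    def _check_fitted(self) -> None:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit() first")
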
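"""Reference configurations for desk-scale (CPU, minutes) experiments.

The full 512x512 / MiT-B0 recipe is impractical without a GPU, so the
reduced preset shrinks widths and depths while keeping every architectural
ingredient (four stages, efficient attention, Mix-FFN, GCSA per stage,
all-MLP decoder): 200 synthetic 64x64 blob patches split 7:2:1, widths
8/16/24/32 at depth 1 each, 10 epochs at the published optimization
hyperparameters.
"""

from __future__ import annotations

from .model import ModelConfig
from .synthetic import SynthSpec, TextureSpec
from .train import TrainConfig

DESK_N_PATCHES = 200
DESK_PATCH = 64


def reduced_model_config(gcsa_enabled: bool = True) -> ModelConfig:
    return ModelConfig(stage_channels=(8, 16, 24, 32), stage_depths=(1, 1, 1, 1),
                       stage_heads=(1, 2, 2, 4), sr_ratios=(8, 4, 2, 1),
                       decoder_dim=64, gcsa_enabled=gcsa_enabled,
                       patch_size=DESK_PATCH)


def desk_train_config(seed: int = 0) -> TrainConfig:
    return TrainConfig(epochs=10, seed=seed)


def desk_synth_spec(seed: int = 0) -> SynthSpec:
    """64x64 patches with 1-3 blob-sized lesions at the default stain palette."""
    return SynthSpec(seed=seed, width=DESK_PATCH, height=DESK_PATCH, n_blobs=2,
                     blob_radius_range=(6.0, 16.0))
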
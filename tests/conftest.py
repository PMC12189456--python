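import numpy as np
import pytest

from gcsaseg.attention import (init_channel_attention_params,
                               init_spatial_attention_params)
from gcsaseg.model import ModelConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ca_params4(rng):
    return init_channel_attention_params(4, rng)


@pytest.fixture
def sa_params4(rng):
    return init_spatial_attention_params(4, rng)


@pytest.fixture(scope="session")
def tiny_config():
    """Smallest config that still exercises every stage and the GCSA blocks."""
    return ModelConfig(stage_channels=(4, 8, 8, 8), stage_depths=(1, 1, 1, 1),
                       stage_heads=(1, 1, 2, 2), sr_ratios=(4, 2, 1, 1),
                       decoder_dim=8, patch_size=32)
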
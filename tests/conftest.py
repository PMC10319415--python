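import numpy as np
import pytest

from vityield.attention_vit import ViTConfig
from vityield.synthetic_data import (
    SceneParams, YieldModelParams, default_seed_effects, generate_dataset,
)
from vityield.temporal_transformer import TemporalConfig


@pytest.fixture(scope="session")
def tiny_vit_config():
    return ViTConfig(image_size=32, patch_size=16, embed_dim=16, depth=1,
                     heads=2)


@pytest.fixture(scope="session")
def tiny_temporal_config():
    return TemporalConfig(embed_dim=16, depth=1, heads=2, out_dim=16)


@pytest.fixture(scope="session")
def small_scene():
    return SceneParams(image_size=(32, 32), row_spacing=8)


@pytest.fixture(scope="session")
def small_dataset(small_scene):
    params = YieldModelParams(
        seed_effects=default_seed_effects(51, rng_seed=0))
    return generate_dataset(24, small_scene, params, rng_seed=0,
                            write_images=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
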
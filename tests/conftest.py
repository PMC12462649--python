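import numpy as np
import pytest

from petmri3d.model import ModelConfig, build_model
from petmri3d.phantoms import PhantomConfig, generate_dataset


@pytest.fixture(scope="session")
def tiny_model_config() -> ModelConfig:
    """Smallest architecture that exercises every block."""
    return ModelConfig(in_channels=1, stage_filters=(4, 8), dense_units=16,
                       lr0=1e-3, seed=0)


@pytest.fixture(scope="session")
def tiny_model(tiny_model_config):
    return build_model(tiny_model_config)


@pytest.fixture(scope="session")
def small_phantom_config() -> PhantomConfig:
    return PhantomConfig(shape=(16, 16, 12), tumour_radius_range=(1.5, 2.5),
                         brain_depth_fraction=0.25, seed=11)


@pytest.fixture(scope="session")
def small_phantoms(small_phantom_config):
    return generate_dataset(small_phantom_config, 10)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
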
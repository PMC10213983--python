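import numpy as np
import pytest

from somnexit.efem import EfemConfig
from somnexit.heads import EncoderConfig
from somnexit.model import MODALITIES, ModelConfig, MultiExitModel
from somnexit.signals import SyntheticDatasetConfig, synthesize_dataset


def tiny_model_config(input_length: int = 3000) -> ModelConfig:
    """Smallest configuration that exercises every architectural element."""
    small = (("conv", 8, 64, 8), ("pool", 8, 8),
             ("conv", 8, 8, 1), ("conv", 8, 8, 1), ("pool", 4, 4))
    large = (("conv", 8, 512, 64),
             ("conv", 8, 6, 1), ("conv", 8, 6, 1), ("pool", 8, 3))
    efem = EfemConfig(small_branch=small, large_branch=large, cbam_reduction=4)
    enc = EncoderConfig(n_heads=4, ff_dim=8, head_hidden=16)
    return ModelConfig(
        input_length=input_length,
        efem={m: efem for m in MODALITIES},
        encoder={m: enc for m in MODALITIES},
    )


@pytest.fixture(scope="session")
def tiny_config():
    return tiny_model_config()


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return MultiExitModel(tiny_config, seed=7)


@pytest.fixture(scope="session")
def small_dataset():
    return synthesize_dataset(SyntheticDatasetConfig(n_epochs=60, seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
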
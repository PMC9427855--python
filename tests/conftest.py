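"""Shared fixtures: tiny phantom datasets sized for fast unit tests."""

import numpy as np
import pytest

from taucl.nn import CNNConfig
from taucl.synthetic import SyntheticConfig, generate_atlas, generate_dataset


@pytest.fixture(scope="session")
def tiny_config() -> SyntheticConfig:
    """16x20x16 grid, 30 subjects: enough structure for every stage."""
    return SyntheticConfig(grid_shape=(16, 20, 16), n_subjects=30, seed=11)


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    cohort, atlas, volumes = generate_dataset(tiny_config)
    return {"config": tiny_config, "cohort": cohort, "atlas": atlas,
            "volumes": volumes}


@pytest.fixture(scope="session")
def tiny_atlas(tiny_config):
    return generate_atlas(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fast_cnn_config():
    """Training config small enough for seconds-long fits in unit tests."""
    return CNNConfig(channels=(4, 8), dense_widths=(8,), max_epochs=15,
                     patience=10, batch_size=8, seed=5)
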
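import numpy as np
import pytest

from protospec.encoder import EncoderConfig
from protospec.preprocess import PreprocessConfig, preprocess_dataset
from protospec import synthetic


@pytest.fixture(scope="session")
def tiny_encoder_config():
    """Three-block encoder small enough for fast training tests."""
    return EncoderConfig(channels=(4, 6, 8), kernel_sizes=(5, 3, 3),
                         pool_sizes=(2, 2, 2), final_pool_length=4,
                         dropout=0.2, input_length=64, feature_dim=32)


@pytest.fixture(scope="session")
def tiny_preprocess_config():
    # narrow window around the discriminating 960 band: at 64 points the full
    # default window would dilute the band shift below the grid resolution
    return PreprocessConfig(trim_lo=800.0, trim_hi=1120.0, n_points=64)


@pytest.fixture(scope="session")
def ivory_small():
    """Two broad-band classes, 24 spectra each, on the default grid."""
    return synthetic.generate_dataset(synthetic.ivory_recipes(), 24, seed=7)


@pytest.fixture(scope="session")
def ivory_small_matrix(ivory_small):
    X, grid = preprocess_dataset(ivory_small)
    return X, grid, list(ivory_small.labels)


@pytest.fixture(scope="session")
def ivory_tiny_matrix(ivory_small, tiny_preprocess_config):
    """Same spectra on the 64-point grid for the tiny encoder."""
    X, grid = preprocess_dataset(ivory_small, tiny_preprocess_config)
    return X, grid, list(ivory_small.labels)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
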
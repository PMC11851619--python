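import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from fdosr.network import DecoderConfig, EncoderConfig
from fdosr.phantom import make_corpus
from fdosr.volume import Volume3D


TINY_ENCODER = EncoderConfig(
    n_rdb=2, layers_per_rdb=3, base_channels=32, growth_channels=8, feature_dim=32
)
TINY_DECODER = DecoderConfig(n_layers=4, hidden_width=32)

# an even smaller configuration for gradient-flow and equivariance checks
MICRO_ENCODER = EncoderConfig(
    n_rdb=2, layers_per_rdb=2, base_channels=4, growth_channels=3, feature_dim=6
)
MICRO_DECODER = DecoderConfig(n_layers=3, hidden_width=5)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_volume_16():
    data = np.random.default_rng(7).random((16, 16, 16))
    return Volume3D(data)


@pytest.fixture(scope="session")
def phantom_corpus_small():
    """Four 32^3 phantoms, one per contrast profile."""
    return make_corpus(4, (32, 32, 32), base_seed=50)
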
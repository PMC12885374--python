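import numpy as np
import pytest

from fleaselect.synthetic import SyntheticSpec, generate_features


@pytest.fixture(scope="session")
def planted():
    """Small planted-signal dataset shared by read-only tests."""
    spec = SyntheticSpec(
        n_per_class=10,
        n_classes=8,
        n_features=64,
        n_informative=8,
        class_separation=6.0,
        noise_sd=1.0,
        seed=7,
    )
    return generate_features(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
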
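import numpy as np
import pytest
from hypothesis import settings

from gogrow import ModelParameters, synthetic_brain, seed_tumor

settings.register_profile("ci", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def params():
    return ModelParameters()


@pytest.fixture
def small_domain():
    """A 48x48 phantom, large enough for short dynamical tests."""
    return synthetic_brain(shape=(48, 48), seed=0)


@pytest.fixture
def seeded_state(small_domain, params):
    return seed_tumor(small_domain, None, params)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
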
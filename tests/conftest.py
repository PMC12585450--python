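import numpy as np
import pytest

from coordgait import GaitSimConfig, generate_trial


@pytest.fixture(scope="session")
def default_trial():
    """A 10-stride synthetic trial under the default study conditions."""
    return generate_trial(GaitSimConfig(n_strides=10, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
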
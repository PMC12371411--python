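import numpy as np
import pytest

from flairwm import default_protocols, generate_template


@pytest.fixture(scope="session")
def template24():
    """A small head template shared by fast tests."""
    return generate_template((24, 24, 24), seed=1)


@pytest.fixture(scope="session")
def template32():
    return generate_template((32, 32, 32), seed=1)


@pytest.fixture(scope="session")
def protocols():
    return default_protocols(4)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
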
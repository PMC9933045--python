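import numpy as np
import pytest

from tandemid import default_config


@pytest.fixture(scope="session")
def carbon_config():
    return default_config("C")


@pytest.fixture(scope="session")
def nitrogen_config():
    return default_config("N")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
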
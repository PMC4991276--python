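import numpy as np
import pytest

from opto import GridSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid8():
    return GridSpec(8, 8)


@pytest.fixture
def grid20():
    return GridSpec(20, 20)
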
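import numpy as np
import pytest

from audlfp import RunConfig


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def narrow_config():
    """Config with the wavelet grid restricted to the ASSR band (fast)."""
    return RunConfig(freq_min=35.0, freq_max=45.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
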
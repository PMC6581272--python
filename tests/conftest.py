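import numpy as np
import pytest

from ribofrag import ModelParams


@pytest.fixture
def unit_params():
    """Standard rate constants: k_f = k_b = k_x = k_y = 1, no transfer."""
    return ModelParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
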
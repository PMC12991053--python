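import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)


@pytest.fixture
def two_level_x(rng):
    """200 bins, level 0 then 1 with a boundary at bin 100, noise SD 0.1."""
    x = np.concatenate([np.zeros(100), np.ones(100)])
    return x + rng.normal(0.0, 0.1, 200)
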
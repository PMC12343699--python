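import numpy as np
import pytest

import permclean as pc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def light_config():
    """Pipeline config with light smoothing for fast, low-noise scenarios."""
    return pc.PipelineConfig(smoother=pc.SmootherSpec("gaussian", w=15))


@pytest.fixture
def flat_plateau():
    """A flat noiseless baseline trace long enough to leave warm-up."""
    return np.full(600, 10.0)
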
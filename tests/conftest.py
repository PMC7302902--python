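import numpy as np
import pytest

from hepafe import phantom as ph


@pytest.fixture
def mgre_acq():
    return ph.default_mgre_acquisition()


@pytest.fixture
def small_scene():
    """Low-noise 48x48 default scene for fast image-path tests."""
    return ph.build_scene(shape=(48, 48), noise_sigma=0.2, seed=123)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
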
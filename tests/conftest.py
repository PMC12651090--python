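import numpy as np
import pytest

from msdtcn.config import SynthConfig
from msdtcn.synth import generate_sample


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_samples():
    """Four 96x96 synthetic dermoscopy samples for engine-level tests."""
    cfg = SynthConfig(image_size=96, hair_count=3)
    return [generate_sample(cfg, seed=500 + i) for i in range(4)]
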
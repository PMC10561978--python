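import numpy as np
import pytest

import stomakit as sk


@pytest.fixture(scope="session")
def small_sample() -> sk.SynthSample:
    """One deterministic 256×256 synthetic sample with a few stomata."""
    return sk.generate_sample(sk.SynthConfig.test_scale(seed=7), 7)


@pytest.fixture(scope="session")
def lite_model() -> sk.RotatedStomataNet:
    return sk.RotatedStomataNet(sk.NetConfig(), seed=0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
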
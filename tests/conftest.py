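import numpy as np
import pytest

from kneeplan.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def phantom64():
    """One small deterministic phantom shared across tests."""
    return generate_phantom(PhantomConfig(image_size=(64, 64), seed=7), 0)


@pytest.fixture(scope="session")
def phantom256():
    return generate_phantom(PhantomConfig(image_size=(256, 256), seed=7), 1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
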
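import numpy as np
import pytest

from octfluid.phantom import PhantomConfig, generate_dataset, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomConfig(seed=11), 11)


@pytest.fixture(scope="session")
def contrast_images():
    """Small controlled-contrast dataset shared across training tests."""
    return generate_dataset(12, PhantomConfig.high_contrast(), 7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
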
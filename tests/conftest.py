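import numpy as np
import pytest

from cineqc.phantom import PhantomParams, generate_phantom


@pytest.fixture(scope="session")
def phantom():
    """One default healthy phantom subject (image, labels)."""
    return generate_phantom(PhantomParams(seed=11))


@pytest.fixture(scope="session")
def phantom_image(phantom):
    return phantom[0]


@pytest.fixture(scope="session")
def phantom_labels(phantom):
    return phantom[1]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
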
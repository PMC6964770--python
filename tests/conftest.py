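import numpy as np
import pytest

from dualpath3d import PhantomSpec, generate_phantom, preprocess


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_phantom():
    """A 48^3 phantom with two lesions, reused across read-only tests."""
    spec = PhantomSpec(volume_shape=(48, 48, 48), tumor_count_range=(2, 2), seed=11)
    return generate_phantom(spec)


@pytest.fixture(scope="session")
def preprocessed_phantom(small_phantom):
    vol, labels = small_phantom
    return preprocess(vol), labels
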
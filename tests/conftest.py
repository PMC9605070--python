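import numpy as np
import pytest

from vesselseg import PhantomSpec, add_artifacts, generate_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """A 48^3 phantom with artifacts, shared across tests that only read it."""
    spec = PhantomSpec(shape=(48, 48, 48), n_trees=2, seed=7)
    vol, label = generate_phantom(spec)
    return add_artifacts(vol, spec), label
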
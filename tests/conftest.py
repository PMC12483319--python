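import numpy as np
import pytest

from synrec import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """10 vesicles in a 48x96x96 volume at 1.554 nm voxels."""
    spec = PhantomSpec(shape=(48, 96, 96), n_vesicles=10, seed=1)
    vol, labels = generate_phantom(spec)
    return spec, vol, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
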
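import numpy as np
import pytest

from flairseg.io_preprocess import Volume
from flairseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_volume():
    """A small noisy volume with a box mask, for preprocessing tests."""
    gen = np.random.default_rng(0)
    data = gen.normal(100.0, 20.0, (4, 24, 24))
    mask = np.zeros(data.shape, dtype=bool)
    mask[:, 4:20, 4:20] = True
    return Volume(data=data, spacing=(5.0, 1.0, 1.0), brain_mask=mask, case_id="small")


# one phantom shared across tests that only read it
@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomSpec(seed=3))


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, fast phantom recipe used where full size is unnecessary."""
    return PhantomSpec(shape=(6, 48, 48), tumour_radius=7.0, seed=0)
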
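import numpy as np
import pytest

from wmh_bullseye import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """64³ phantom, 3 lesions at the default 5-SD T2 contrast."""
    spec = PhantomSpec(rng_seed=11)
    t1, t2, truth = generate_phantom(spec)
    return spec, t1, t2, truth


@pytest.fixture(scope="session")
def noise_free_phantom():
    spec = PhantomSpec(rng_seed=7, noise_sd=0.0)
    t1, t2, truth = generate_phantom(spec)
    return spec, t1, t2, truth


@pytest.fixture(scope="session")
def small_phantom():
    """48³ phantom used where full resolution is not needed."""
    spec = PhantomSpec(grid_shape=(48, 48, 48), lesion_count=2, rng_seed=5)
    t1, t2, truth = generate_phantom(spec)
    return spec, t1, t2, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
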
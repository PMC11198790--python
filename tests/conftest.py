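import numpy as np
import pytest

from baoscnn.search_space import default_seagrass_space, desk_space
from baoscnn.synthetic_data import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def table1_space():
    return default_seagrass_space()


@pytest.fixture(scope="session")
def small_space():
    return desk_space()


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small separable 4-class dataset for fast training tests."""
    spec = SyntheticSpec(per_class=15, image_size=(12, 12), noise_sd=0.05, seed=7)
    return generate_dataset(spec)
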
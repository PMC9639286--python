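import numpy as np
import pytest
from hypothesis import settings

from taucog.config import SimulationConfig
from taucog.synthetic import generate_atlas, generate_cohort

settings.register_profile("det", derandomize=True, max_examples=50)
settings.load_profile("det")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced cohort that keeps every group and the mixture fit viable."""
    return SimulationConfig.adni_like(
        counts={"CN_NEG": 50, "CN_POS": 25, "MCI_POS": 20, "DEM_POS": 10},
        grid_dims=(12, 12, 12),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def atlas20():
    atlas, maps = generate_atlas((20, 20, 20), seed=1)
    return atlas, maps


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
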
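import numpy as np
import pytest
from hypothesis import settings

from aphasiakit.simulate import CohortSpec, simulate_cohorts

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    return CohortSpec(
        seed=42, n_nhi_young=8, n_nhi_elderly=6, n_pwa_young=8, n_pwa_elderly=6
    )


@pytest.fixture(scope="session")
def default_cohorts():
    """One default-sized control + patient draw shared across tests."""
    return simulate_cohorts(CohortSpec(seed=20240901))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
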
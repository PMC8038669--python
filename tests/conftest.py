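import numpy as np
import pytest

from octa_density import CohortSpec, generate_cohort, generate_vessel_network


@pytest.fixture(scope="session")
def recentered_cohort():
    """Default synthetic cohort with exact group means and SDs."""
    return generate_cohort(CohortSpec(seed=7, recenter=True))


@pytest.fixture(scope="session")
def sampled_cohort():
    """Cohort drawn without recentering (pure sampling mode)."""
    return generate_cohort(CohortSpec(seed=11, recenter=False))


@pytest.fixture(scope="session")
def small_network():
    """A small noise-free vessel network for fast image-chain tests."""
    return generate_vessel_network(
        seed=3,
        grid=(128, 128),
        n_seeds=30,
        branch_params={"max_branches": 80},
        noise_level=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
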
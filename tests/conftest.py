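import numpy as np
import pytest

from cats_ards.synthetic import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: planted structure strong enough to recover."""
    return SimulationConfig(
        n_subjects=48, n_genes=300, k_true=3, n_informative=60,
        effect_size=2.0, noise_sd=1.0,
        subtype_proportions=(16 / 48, 16 / 48, 16 / 48),
        immunocompromised_prev=(0.3, 0.5, 0.1),
        death_prob_28d=(0.3, 0.25, 0.1),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
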
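import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gmrepro import SyntheticSpec, make_template, salmon_scheme, simulate_dataset

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def template():
    return make_template()


@pytest.fixture(scope="session")
def scheme():
    return salmon_scheme()


@pytest.fixture(scope="session")
def small_spec():
    """Reduced-size study: 2 rivers x 4 operators, 50 fish, 5 replicated.

    The group effect is boosted relative to the default so that the
    between-river tests keep power at this reduced sample size.
    """
    return SyntheticSpec(n_per_group={"Spey": 24, "Oykel": 26},
                         n_replicate_per_group=5, seed=7,
                         group_effect_magnitude=0.02)


@pytest.fixture(scope="session")
def small_data(small_spec):
    return simulate_dataset(small_spec)


@pytest.fixture(scope="session")
def clean_spec():
    """No operator bias, no trial noise: every digitisation is exact."""
    return SyntheticSpec(n_per_group={"Spey": 12, "Oykel": 12},
                         n_replicate_per_group=4,
                         operator_bias_magnitude=0.0, trial_noise_sd=0.0,
                         seed=11)


@pytest.fixture(scope="session")
def clean_data(clean_spec):
    return simulate_dataset(clean_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
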
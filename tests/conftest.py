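import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from breastdti.features import prepare_features
from breastdti.gradients import make_gradient_scheme
from breastdti.simulate import CohortConfig, simulate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scheme():
    """Default 13-volume acquisition: b = 0, 100, 800 with 6 directions."""
    return make_gradient_scheme()


@pytest.fixture(scope="session")
def cohort():
    """A moderate synthetic cohort shared by modeling tests."""
    df, truth = simulate_cohort(CohortConfig(n_patients=300, seed=11))
    return df


@pytest.fixture(scope="session")
def feature_matrix(cohort):
    return prepare_features(cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
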
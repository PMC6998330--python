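import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def training_spec():
    """Full-design training cohort spec: 16 subjects, 3 muscles, 2 views."""
    from swerel.simulate import CohortSpec

    return CohortSpec(cohort="training", n_subjects=16, missing_rate=0.0, seed=7)


@pytest.fixture
def training_table(training_spec):
    from swerel.simulate import generate_cohort

    return generate_cohort(training_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
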
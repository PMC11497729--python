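import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort shared by tests that only need realistic structure."""
    import amyloidcast as ac

    return ac.generate_cohort(120, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
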
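import numpy as np
import pytest

from revlearn.cohort import small_cohort_fixture
from revlearn.models import EWAParams, simulate_agent
from revlearn.task import build_default_task


@pytest.fixture(scope="session")
def default_task():
    return build_default_task()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixture_cohort():
    """26-subject synthetic cohort with the full group/component structure."""
    return small_cohort_fixture(seed=7)


@pytest.fixture(scope="session")
def ewa_session(default_task):
    """One well-behaved EWA agent session on the default task."""
    rng = np.random.default_rng(99)
    return simulate_agent(
        "ewa", EWAParams(phi=0.7, rho=0.3, beta=3.5), default_task, rng
    )
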
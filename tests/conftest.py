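import pytest

from homingcues.environment import build_environment
from homingcues.geometry import standard_course
from homingcues.metrics import summarize_performance
from homingcues.synthetic import default_cohort, simulate_study


@pytest.fixture(scope="session")
def course():
    return standard_course()


@pytest.fixture(scope="session")
def env3():
    return build_environment(3, seed=1)


@pytest.fixture(scope="session")
def full_study():
    """A full-size simulated study: 23 participants x 6 conditions x 24 reps."""
    return simulate_study(default_cohort(23, seed=1), seed=1)


@pytest.fixture(scope="session")
def study_summary(full_study):
    return summarize_performance(full_study)
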
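import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from caries_cea import AgeSchedule, ModelConfig, default_config

settings.register_profile(
    "ci",
    max_examples=50,
    derandomize=True,
    suppress_health_check=[
        HealthCheck.too_slow,
        # fixtures used inside @given are read-only parameter sets
        HealthCheck.function_scoped_fixture,
    ],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    """Bundled default parameter set (published input-table values)."""
    return default_config()


@pytest.fixture
def config(default_params):
    return default_params[0]


@pytest.fixture
def specs(default_params):
    return default_params[1]


@pytest.fixture
def flat_schedule():
    """Constant schedule over the full 10-year horizon."""
    n = 10
    return AgeSchedule(
        ages=np.arange(5, 5 + n),
        prob_caries=np.full(n, 0.2),
        prob_exit=np.full(n, 0.03),
        baseline_dmft=np.full(n, 2.5),
    )


@pytest.fixture
def mini_config():
    """2-cycle miniature for hand-checkable ledgers."""
    return ModelConfig(cohort_size=10, start_age=5, exit_age=7)


def make_flat_schedule(n, p_caries, p_exit, dmft=1.0, start_age=5):
    return AgeSchedule(
        ages=np.arange(start_age, start_age + n),
        prob_caries=np.full(n, p_caries),
        prob_exit=np.full(n, p_exit),
        baseline_dmft=np.full(n, dmft),
    )
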
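import pytest
from hypothesis import settings

from devaltask import RLParams, generate_schedule, rl_model, synthetic_data

settings.register_profile("suite", max_examples=25, deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schedule():
    return generate_schedule(seed=1)


@pytest.fixture(scope="session")
def rl_trials(schedule):
    params = RLParams(alpha=0.3, beta0=1.5, beta_slope=0.75, tau0=0.5, tau_slope=0.0)
    trials = rl_model.simulate_learning(schedule, params, rng_seed=42)
    trials["subject"] = "s1"
    return trials


@pytest.fixture(scope="session")
def bayes_trials(schedule):
    trials = synthetic_data.simulate_bayes_subject(schedule, lam=0.85, rng_seed=7)
    trials["subject"] = "s2"
    return trials


@pytest.fixture(scope="session")
def small_cohort():
    spec = synthetic_data.CohortSpec(n_per_group=6, seed=3)
    return synthetic_data.generate_cohort(spec)
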
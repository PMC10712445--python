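import numpy as np
import pytest

from efficacy_hgf.fitting import FitOptions, fit_map
from efficacy_hgf.models import get_model
from efficacy_hgf.task import TaskConfig, generate_schedule, simulate_session


@pytest.fixture(scope="session")
def default_task() -> TaskConfig:
    return TaskConfig()


@pytest.fixture(scope="session")
def us3_model():
    return get_model("3L_us")


@pytest.fixture(scope="session")
def us3_agent(us3_model):
    values = dict(omega2_choice=-5.0, omega2_nochoice=-5.5,
                  omega3_choice=-6.0, omega3_nochoice=-6.0)
    agent, resp = us3_model.build_agent(values)
    return values, agent, resp


@pytest.fixture(scope="session")
def played_session(default_task, us3_model, us3_agent):
    """One deterministic 54-trial session played by a 3-level agent."""
    _, agent, resp = us3_agent
    schedule = generate_schedule(default_task, seed=11)
    return simulate_session(schedule, agent, resp, us3_model, seed=12)


@pytest.fixture(scope="session")
def fitted_session(played_session, us3_model):
    return fit_map(played_session, us3_model, FitOptions(n_starts=4, seed=0))


def random_hgf_draws(n, seed, n_levels=3):
    """Random (state, input, params) draws in sane ranges for oracle tests."""
    rng = np.random.default_rng(seed)
    draws = []
    for _ in range(n):
        draws.append(dict(
            mu2=rng.normal(0, 2),
            sigma2=rng.uniform(0.05, 4.0),
            mu3=rng.normal(1, 1),
            sigma3=rng.uniform(0.05, 4.0),
            omega2=rng.uniform(-9, -1),
            omega3=rng.uniform(-9, -3),
            kappa=rng.uniform(0.2, 2.0),
            u=int(rng.integers(2)),
            n_levels=n_levels,
        ))
    return draws
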
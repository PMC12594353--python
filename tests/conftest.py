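import numpy as np
import pandas as pd
import pytest

from revlearn.inference import HierarchicalModel, natural_to_unconstrained
from revlearn.models import MODELS, simulate_agent
from revlearn.task import TaskConfig, generate_schedule


@pytest.fixture
def rng():
    return np.random.default_rng(20250929)


@pytest.fixture(scope="session")
def hvln_schedule():
    return generate_schedule(TaskConfig.from_condition("HVLN"), np.random.default_rng(7))


@pytest.fixture(scope="session")
def rw_cohort():
    """12 agents simulated from known RW group-level hyperparameters on one
    high-volatility low-noise block (shared by several inference tests)."""
    spec = MODELS["RW"]
    mu_nat = np.array([0.35, 2.5])
    mu_u = natural_to_unconstrained(spec, mu_nat)
    sigma_u = np.array([0.25, 0.25])
    rng = np.random.default_rng(11)
    schedule = generate_schedule(TaskConfig.from_condition("HVLN"), np.random.default_rng(7))
    frames = []
    true_params = []
    for i in range(12):
        u = mu_u + sigma_u * rng.standard_normal(2)
        theta = np.array([_phi(u[0]), 10.0 * _phi(u[1])])
        true_params.append(theta)
        frame = simulate_agent(spec, theta, schedule, rng)
        frame.insert(0, "subjID", f"s{i:02d}")
        frames.append(frame)
    data = pd.concat(frames, ignore_index=True)
    return {
        "data": data,
        "schedule": schedule,
        "mu_u": mu_u,
        "sigma_u": sigma_u,
        "mu_nat": mu_nat,
        "true_params": np.asarray(true_params),
    }


def _phi(u):
    from scipy.special import ndtr

    return float(ndtr(u))


@pytest.fixture(scope="session")
def rw_fit(rw_cohort):
    """One converged hierarchical RW fit of the shared cohort."""
    fit = HierarchicalModel(model="RW", chains=2, warmup=500, draws=500, seed=3).fit(
        rw_cohort["data"]
    )
    assert fit.converged_, "shared fixture fit must converge for downstream tests"
    return fit
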
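import numpy as np
import pandas as pd
import pytest

import elemove as em


@pytest.fixture(scope="session")
def well_separated_params() -> em.HmmParams:
    """Clearly distinct encamped/exploratory emission regimes."""
    return em.HmmParams(
        mu=np.array([100.0, 1000.0]),
        sigma=np.array([80.0, 600.0]),
        angle_mean=np.array([0.0, 0.0]),
        kappa=np.array([0.5, 2.0]),
        tpm=np.array([[0.9, 0.1], [0.1, 0.9]]),
    )


@pytest.fixture(scope="session")
def simulated_steps(well_separated_params):
    """20,000 simulated steps with their true state path."""
    return em.simulate_hmm_track(well_separated_params, 20_000, seed=42)


@pytest.fixture(scope="session")
def fitted_hmm(simulated_steps):
    steps, _ = simulated_steps
    return em.fit_hmm(steps, n_restarts=10, seed=7)


def make_trajectory(
    hours: int,
    start: str = "2016-01-01",
    step_m: float = 500.0,
    seed: int = 0,
    individual_id: str = "e1",
) -> em.Trajectory:
    """Random-walk trajectory at hourly fixes, burst-segmented."""
    rng = np.random.default_rng(seed)
    angles = rng.uniform(-np.pi, np.pi, hours)
    steps = rng.gamma(2.0, step_m / 2.0, hours)
    x = np.concatenate([[0.0], np.cumsum(steps * np.cos(angles))])
    y = np.concatenate([[0.0], np.cumsum(steps * np.sin(angles))])
    t = pd.date_range(start, periods=hours + 1, freq="h")
    tr = em.Trajectory(
        individual_id=individual_id,
        sex="female",
        region="r1",
        fixes=pd.DataFrame({"t_utc": t, "t_local": t, "x": x, "y": y, "burst": -1}),
    )
    return em.segment_bursts(tr)


@pytest.fixture
def hourly_track():
    return make_trajectory(48)


@pytest.fixture(scope="session")
def univariate_recovery():
    """Behavior table simulated at the reference variance components
    (V_I = 0.3, V_month = 0.1, V_resid = 0.6, beta_sex = 0.5; 96 x 18),
    with its ground truth and a fitted univariate model."""
    tab, truth = em.simulate_behavior_table(
        96, 18, beta=np.array([0.5, 0.0, 0.0, 0.0, 0.0]),
        sigma_individual=0.3, v_region=0.0, v_month=0.1,
        sigma_residual=0.6, seed=101,
    )
    spec = em.ModelSpec(response="y", random=("individual", "month"), seed=7)
    return tab, truth, em.fit_univariate(tab, spec)
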
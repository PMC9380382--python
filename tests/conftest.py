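import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ncctrends import ScenarioSpec, TrendSpec, make_design

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def two_period_design():
    """Two-period design: 125/125 controls and arm 1, 250 arm 2 in period 2."""
    return make_design([[125, 125], [125, 125], [0, 250]])


@pytest.fixture(scope="session")
def cont_scenario(two_period_design):
    """Continuous endpoint, equal step trends, both treatments effective."""
    return ScenarioSpec(
        design=two_period_design,
        trend=TrendSpec("step", 0.15),
        endpoint="continuous",
        eta0=0.0,
        effects=(0.25, 0.25),
        sigma=1.0,
    )


@pytest.fixture(scope="session")
def binary_scenario(two_period_design):
    """Binary endpoint, control rate 0.7, equal step trends."""
    return ScenarioSpec(
        design=two_period_design,
        trend=TrendSpec("step", 0.25),
        endpoint="binary",
        p0=0.7,
        odds_ratios=(1.8, 1.8),
    )


def random_two_period(rng, max_cell=8):
    """A small random two-period trial: counts, arrays and cell means.

    Returns (counts 3x2, arm, period, j, y, ybar 3x2) with n[2, 1] = 0 and
    outcomes drawn with arbitrary cell-specific means.
    """
    n = rng.integers(2, max_cell + 1, size=(3, 2))
    n[2, 0] = 0
    arm = np.concatenate([
        np.repeat([0, 1], n[:2, 0]),
        np.repeat([0, 1, 2], n[:, 1]),
    ])
    period = np.concatenate([np.ones(n[:, 0].sum(), int), np.full(n[:, 1].sum(), 2)])
    j = np.arange(1.0, arm.size + 1.0)
    mu = rng.normal(0, 2, size=(3, 2))
    y = mu[arm, period - 1] + rng.standard_normal(arm.size)
    ybar = np.full((3, 2), np.nan)
    for k in range(3):
        for s in (1, 2):
            sel = (arm == k) & (period == s)
            if sel.any():
                ybar[k, s - 1] = y[sel].mean()
    return n, arm, period, j, y, ybar


@pytest.fixture
def make_random_trial():
    return random_two_period


@pytest.fixture
def canonical_dataset(cont_scenario):
    from ncctrends import simulate_trial

    return simulate_trial(cont_scenario, seed=7)


@pytest.fixture
def canonical_binary_dataset(binary_scenario):
    from ncctrends import simulate_trial

    return simulate_trial(binary_scenario, seed=8)


def cell_means_frame(df: pd.DataFrame) -> np.ndarray:
    """3 x 2 cell means from a canonical two-period dataset."""
    out = np.full((3, 2), np.nan)
    for (k, s), v in df.groupby(["arm", "period"])["y"].mean().items():
        out[int(k), int(s) - 1] = v
    return out
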
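import numpy as np
import pandas as pd
import pytest

from kmipd.preprocess import preprocess
from kmipd.reconstruct import reconstruct_ipd
from kmipd.simulate import SimConfig, simulate_trial


@pytest.fixture(scope="session")
def trial30():
    """One simulated trial at the default design (30% censoring, 3-month table)."""
    return simulate_trial(SimConfig(seed=11))


@pytest.fixture(scope="session")
def treat_arm(trial30):
    return trial30.arms["treatment"]


@pytest.fixture(scope="session")
def treat_prep(treat_arm):
    return preprocess(treat_arm.points, risk=treat_arm.risk)


@pytest.fixture(scope="session")
def treat_recon(treat_prep):
    ipd, est = reconstruct_ipd(treat_prep, arm="treatment")
    return ipd, est


@pytest.fixture
def hand_ipd():
    """Four subjects: events at 1 and 2, censored at 1.5 and 3.

    Hand product-limit: S(1) = 3/4, S(2) = 3/4 * 1/2 = 0.375;
    Greenwood SE(1) = 0.75*sqrt(1/12) ~ 0.2165; cumulative hazard
    0.25 then 0.75.
    """
    return pd.DataFrame(
        {"time": [1.0, 1.5, 2.0, 3.0], "status": [1, 0, 1, 0], "arm": 0}
    )


def make_points(times, surv):
    return np.column_stack([np.asarray(times, float), np.asarray(surv, float)])
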
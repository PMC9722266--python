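import numpy as np
import pytest

import pupiladapt as pa
from pupiladapt.synthetic_cohort import ChannelConfig, ReachConfig

#: two-block miniature of the abrupt null-field-null design: 55 + 55 reaching
#: trials, field on trials 66-90 (from the 11th trial of block 2), washout
#: from trial 91, exp-1 plant
MINI_SPEC = {
    "blocks": [55, 55],
    "b_full": 0.15,
    "cw_trials": [(66, 90)],
    "amplitude": 0.12,
    "channel": ChannelConfig(7000.0, 30.0),
    "light_reflex_per_side": 2,
    "eye_distance_mm": 160.0,
}


@pytest.fixture(scope="session")
def exp1_schedule():
    return pa.make_schedule("exp1", rng=0)


@pytest.fixture(scope="session")
def mini_schedule():
    return pa.make_schedule(MINI_SPEC, rng=0)


@pytest.fixture(scope="session")
def mini_cohort():
    """Noisy two-block cohort, n=6, for feature/stat plumbing tests."""
    return pa.generate_cohort(MINI_SPEC, 6, seed=20240901)


@pytest.fixture(scope="session")
def mini_table(mini_cohort):
    return pa.build_trial_table(mini_cohort)


@pytest.fixture(scope="session")
def exp2a_cohort():
    """Switching-field cohort, n=5, for the change-point analyses."""
    return pa.generate_cohort("exp2A", 5, seed=7)


@pytest.fixture(scope="session")
def exp2a_table(exp2a_cohort):
    return pa.build_trial_table(exp2a_cohort)


def exp1_reach_cfg(feedback: bool = True) -> ReachConfig:
    kp, kd = (100.0, 10.0) if feedback else (0.0, 0.0)
    return ReachConfig(amplitude=0.12, channel=ChannelConfig(7000.0, 30.0),
                       feedback_kp=kp, feedback_kd=kd)


def exp234_reach_cfg(feedback: bool = True) -> ReachConfig:
    kp, kd = (100.0, 10.0) if feedback else (0.0, 0.0)
    return ReachConfig(amplitude=0.10, channel=ChannelConfig(2500.0, 25.0),
                       feedback_kp=kp, feedback_kd=kd)


def tangential_speed(ts) -> np.ndarray:
    return np.hypot(ts.vel_xy[:, 0], ts.vel_xy[:, 1])
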
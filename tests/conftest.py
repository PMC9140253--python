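import numpy as np
import pytest

from startlehab import (CohortConfig, MotionLimits, StartleTrace,
                        default_generative_params, simulate_cohort)

#: kinematic limit set of the concussive stroke (calibrated default jerk)
APPARATUS_LIMITS = dict(start_position=0.0, end_position=320.0, v_max=5.1,
                        a_max=61.0, d_max=385.0, j_max=45_000.0, dt=1e-3)


@pytest.fixture(scope="session")
def apparatus_limits() -> MotionLimits:
    return MotionLimits(**APPARATUS_LIMITS)


@pytest.fixture(scope="session")
def default_cohort():
    """One full calibrated cohort (72 fish/group x 6 times), fixed seed."""
    return simulate_cohort(CohortConfig(seed=20_220_527))


@pytest.fixture(scope="session")
def generative_params():
    return default_generative_params()


def make_trace(distances, fish_id="f1", group="control", session=1,
               test_time="baseline"):
    return StartleTrace(fish_id=fish_id, group=group, session=session,
                        test_time=test_time,
                        distances=np.asarray(distances, dtype=float))
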
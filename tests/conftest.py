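import warnings

import numpy as np
import pytest

from stereovr.geometry import build_trial_schedule
from stereovr.simulate import (
    CONTROL_PROFILE,
    POSTCOVID_PROFILE,
    simulate_eye_log,
    simulate_participant,
    simulate_responses,
)

warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_schedule():
    """A 9-stimulus design (3 disparities × 3 positions × 1 repetition)."""
    return build_trial_schedule(
        positions=("Central", "Up", "Down"), repetitions=1, seed=3
    )


@pytest.fixture(scope="session")
def small_run(small_schedule):
    """One short control run: (schedule, responses, raw log)."""
    rng = np.random.default_rng(11)
    responses = simulate_responses(small_schedule, CONTROL_PROFILE, rng)
    log = simulate_eye_log(small_schedule, responses, CONTROL_PROFILE, rng)
    return small_schedule, responses, log


@pytest.fixture(scope="session")
def control_participant():
    """A full 81-stimulus control participant."""
    return simulate_participant(
        "C00", "control", CONTROL_PROFILE, np.random.SeedSequence(21)
    )


@pytest.fixture(scope="session")
def patient_participant():
    return simulate_participant(
        "P00", "postcovid", POSTCOVID_PROFILE, np.random.SeedSequence(22)
    )
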
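import numpy as np
import pytest

from petdose import (
    F18,
    MEFWAY_SCHEDULE,
    FrameSchedule,
    NoiseModel,
    Subject,
    TimeActivityCurve,
    simulate_subject,
    synthetic_s_table,
)

LAMBDA_F18 = F18.decay_constant_per_h  # 0.37887... h^-1
MEAN_LIFE_F18 = F18.mean_life_h  # 2.63941... h


@pytest.fixture
def dense_schedule():
    return FrameSchedule.uniform(0, 120, 50)


@pytest.fixture
def mono_exponential_tac(dense_schedule):
    """Noiseless TAC decaying at exactly the physical rate, A0 = 100 MBq."""
    t = dense_schedule.midpoints_h
    return TimeActivityCurve("blob", dense_schedule, 100.0 * np.exp(-LAMBDA_F18 * t))


@pytest.fixture
def hepatobiliary_subject():
    subject, truth = simulate_subject(
        "hepatobiliary", MEFWAY_SCHEDULE, injected_mbq=250.0, noise=NoiseModel(0.0, 0)
    )
    return subject, truth


@pytest.fixture
def renal_subject():
    subject, truth = simulate_subject(
        "renal", MEFWAY_SCHEDULE, injected_mbq=250.0, noise=NoiseModel(0.0, 0)
    )
    return subject, truth


@pytest.fixture
def s_table_for(hepatobiliary_subject):
    subject, _ = hepatobiliary_subject
    return synthetic_s_table(subject.organs, seed=7)
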
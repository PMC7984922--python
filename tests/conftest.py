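import numpy as np
import pytest

from splitgfr import (
    DynamicRenogram,
    InjectionRecord,
    PatientBiometrics,
    RoiSet,
    ToolConfig,
)
from splitgfr.phantom import AcquisitionModel, RaterModel, simulate_cohort


@pytest.fixture
def biometrics():
    return PatientBiometrics(height_cm=170.0, weight_kg=70.0)


@pytest.fixture
def injection():
    return InjectionRecord(
        full_syringe_counts=600_000.0,
        full_count_duration_s=60.0,
        empty_syringe_counts=600.0,
        empty_count_duration_s=6.0,
        full_count_time_offset_s=300.0,
        empty_count_time_offset_s=60.0,
    )


@pytest.fixture
def standard_schedule_renogram():
    """Empty-count renogram on the standard 30x2 s + 20x60 s schedule."""
    starts = np.concatenate([np.arange(30) * 2.0, 60.0 + np.arange(20) * 60.0])
    durations = np.concatenate([np.full(30, 2.0), np.full(20, 60.0)])
    frames = np.zeros((50, 8, 8), dtype=np.int64)
    return DynamicRenogram(frames=frames, frame_start_s=starts, frame_duration_s=durations)


@pytest.fixture
def tiny_study(biometrics, injection):
    """A minimal hand-checkable valid study on a 6x6 grid."""
    frames = np.ones((3, 6, 6), dtype=np.int64)
    renogram = DynamicRenogram(
        frames=frames,
        frame_start_s=np.array([0.0, 2.0, 4.0]),
        frame_duration_s=np.array([2.0, 2.0, 2.0]),
    )
    masks = {
        "left_kidney": np.zeros((6, 6), bool),
        "right_kidney": np.zeros((6, 6), bool),
        "left_background": np.zeros((6, 6), bool),
        "right_background": np.zeros((6, 6), bool),
    }
    masks["left_kidney"][1:3, 1:3] = True
    masks["right_kidney"][1:3, 4:6] = True
    masks["left_background"][4, 0:2] = True
    masks["right_background"][4, 4:6] = True
    return renogram, RoiSet(masks=masks), biometrics, injection


@pytest.fixture(scope="session")
def small_noisy_cohort():
    """A small default-condition cohort reused across tests (seed 7)."""
    return simulate_cohort(n_subjects=6, seed=7)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Expectation-mode cohort with tissue background disabled (seed 7)."""
    acq = AcquisitionModel(poisson_noise=False, background_fraction=0.0)
    return simulate_cohort(n_subjects=6, acquisition=acq, seed=7)


@pytest.fixture
def default_config():
    return ToolConfig()
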
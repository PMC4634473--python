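import numpy as np
import pytest

import wristpose as wp


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def tiny_study():
    """A small but complete 8-class study at 10 Hz (3 subjects x 2 reps)."""
    cfg = wp.SimConfig(n_subjects=3, reps_per_class=2, rate_hz=10, seed=7)
    return wp.simulate_study(cfg)


@pytest.fixture(scope="session")
def tiny_matrix(tiny_study):
    return wp.feature_matrix(tiny_study)


def make_recording(n=500, fs=100.0, subject="s1", accel=None, gyro=None):
    """A quiet 1-g recording with optional channel overrides."""
    t = np.arange(n) / fs
    if accel is None:
        accel = np.tile([0.0, 1.0, 0.0], (n, 1))
    if gyro is None:
        gyro = np.zeros((n, 3))
    return wp.IMURecording(
        subject_id=subject,
        sampling_rate_hz=fs,
        timestamps=t,
        accel=accel,
        gyro=gyro,
    )


def make_window(accel, gyro=None, fs=100.0, label="no_movement"):
    accel = np.asarray(accel, dtype=float)
    if gyro is None:
        gyro = np.zeros_like(accel)
    n = len(accel)
    return wp.AnnotatedWindow(
        subject_id="s1",
        label=label,
        sampling_rate_hz=fs,
        accel=accel,
        gyro=gyro,
        duration_s=n / fs,
    )
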
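import numpy as np
import pytest

from pupilvr.synth import SynthConfig
from pupilvr.trace_io import GazeTrace, PupilTrace

FS = 90.0
DT = 1.0 / FS


def make_grid(t_start=-0.2, t_end=4.0):
    n = int(round((t_end - t_start) * FS)) + 1
    return t_start + DT * np.arange(n)


def make_pupil(values, times=None, valid=None):
    values = np.asarray(values, dtype=float)
    if times is None:
        times = DT * np.arange(values.size)
    if valid is None:
        valid = np.isfinite(values)
    return PupilTrace(times, values, valid)


def make_gaze(x, y, times=None, valid=None):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if times is None:
        times = DT * np.arange(x.size)
    if valid is None:
        valid = np.ones(x.size, dtype=bool)
    return GazeTrace(times, x, y, valid)


@pytest.fixture
def grid():
    return make_grid()


@pytest.fixture
def noisefree_config():
    """Small noise- and artifact-free experiment: the clean-data identity case."""
    return SynthConfig(
        n_subjects=2,
        reps_per_cell=2,
        noise_sd_mm=0.0,
        drift_sd_mm=0.0,
        blink_rate_hz=0.0,
        artifact_prob=0.0,
        gaze_drift_prob=0.0,
        gaze_jitter_deg=0.0,
        seed=11,
    )


@pytest.fixture
def small_config():
    """Small noisy experiment with all artifact classes active."""
    return SynthConfig(n_subjects=3, reps_per_cell=2, seed=5)
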
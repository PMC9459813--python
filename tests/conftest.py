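import numpy as np
import pytest

from stairpower.io import ImuRecording
from stairpower.segmentation import SegmentWindow


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(n=512, fs=128.0, accel=None, gyro="random", seed=0,
                   subject_id="S1", visit_id="V1"):
    """Build a small valid recording; channels default to mild noise."""
    r = np.random.default_rng(seed)
    t = np.arange(n) / fs
    if accel is None:
        accel = 9.81 + 0.1 * r.standard_normal((n, 3))
        accel[:, 1:] -= 9.81
    if isinstance(gyro, str) and gyro == "random":
        gyro = 0.05 * r.standard_normal((n, 3))
    return ImuRecording(time=t, accel=accel, gyro=gyro, fs=fs,
                        subject_id=subject_id, visit_id=visit_id)


def make_window(accel, gyro=None, fs=50.0, label="ascent", **kw):
    return SegmentWindow(accel=np.asarray(accel, dtype=float),
                         gyro=None if gyro is None else np.asarray(gyro, dtype=float),
                         fs=fs, label=label, **kw)


@pytest.fixture
def random_window(rng):
    """A 75-sample six-axis window of plausible magnitude."""
    accel = 9.81 + rng.standard_normal((75, 3))
    gyro = 0.3 * rng.standard_normal((75, 3))
    return make_window(accel, gyro)
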
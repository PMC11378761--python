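import numpy as np
import pytest

from expanding_procrustes.io import CHANNELS, Placement
from expanding_procrustes.synthetic import MotionParams, make_task_curve

IDENTITY_MAP = {name: name for name in ("t", *CHANNELS)}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def reach_curve():
    """A deterministic task-shaped N x 3 curve, long enough to window."""
    return make_task_curve(MotionParams(task="reach", trial_len=200, seed=7, noise_sd=0.01))


@pytest.fixture
def toy_log():
    """Three-row log with all ten columns under vendor-ish names."""
    header = "time,accx,accy,accz,gyrx,gyry,gyrz,ang_r,ang_p,ang_y"
    rows = [
        "0.0,0.1,0.2,0.3,1,2,3,10,20,30",
        "0.1,0.4,0.5,0.6,4,5,6,40,50,60",
        "0.2,0.7,0.8,0.9,7,8,9,70,80,90",
    ]
    column_map = {
        "time": "t",
        "accx": "ax", "accy": "ay", "accz": "az",
        "gyrx": "gx", "gyry": "gy", "gyrz": "gz",
        "ang_r": "roll", "ang_p": "pitch", "ang_y": "yaw",
    }
    return "\n".join([header, *rows]), column_map
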
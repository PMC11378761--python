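"""Synthetic bilateral sensor recordings with known ground truth.

No raw recordings accompany the study this package implements, so every
stage of the pipeline is exercised against generated streams that mimic
the task structure of the three reaching activities:

* ``reach``   -- two forward-acceleration pulses per trial (upper-arm
  launch, then forearm extension);
* ``button`` / ``unbutton`` -- four pulses per trial, one per button,
  finishing at the highest button (largest pulse);
* ``cabinet`` -- asymmetric: one pulse on the dominant arm, two on the
  non-dominant arm (reach to open, return).

Trials are Gaussian acceleration lobes on the forward (y) axis with small
correlated x/z components, separated by near-zero rest baselines so the
local-extrema boundary rules are well-posed.  Values are quantized to the
sensor grids (0.005 g, 0.61 deg/s, 0.05 deg).  Pairs with a planted
congruent interval -- a similarity-transformed copy inside the interval,
independent signal outside -- provide ground truth for the expanding
algorithm's recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (
    ACCEL_RESOLUTION_G,
    ANGLE_RESOLUTION_DEG,
    CHANNELS,
    GYRO_RESOLUTION_DPS,
    Placement,
    SensorStream,
    all_placements,
)
from .segmentation import RepresentativeCurve

__all__ = [
    "MotionParams",
    "SyntheticPair",
    "SubjectRecord",
    "task_pulses",
    "characteristic_peaks",
    "make_task_curve",
    "plant_congruent_pair",
    "simulate_subject",
]

#: pulse layout per task: (center fraction, width fraction, amplitude in g)
_TASK_PULSES = {
    "reach": [(0.30, 0.07, 0.80), (0.62, 0.07, 0.55)],
    "button": [(0.14, 0.035, 0.45), (0.38, 0.035, 0.55), (0.62, 0.035, 0.65), (0.86, 0.035, 0.80)],
    "unbutton": [(0.14, 0.035, 0.45), (0.38, 0.035, 0.55), (0.62, 0.035, 0.65), (0.86, 0.035, 0.80)],
    "cabinet": [(0.50, 0.10, 0.80)],
    "cabinet_nondominant": [(0.28, 0.08, 0.70), (0.72, 0.08, 0.70)],
}

_TRIAL_LEN = {"reach": 33, "button": 160, "unbutton": 160, "cabinet": 60}

#: amplitude (g) of the broad movement envelope spanning a whole trial;
#: keeps the acceleration between within-trial pulses elevated above the
#: resting baseline, as in continuous movement
_TASK_ENVELOPE = {"reach": 0.30, "button": 0.25, "unbutton": 0.25, "cabinet": 0.25}


@dataclass
class MotionParams:
    """Shape and noise of one simulated task recording."""

    task: str
    n_trials: int = 10
    trial_len: int | None = None  # samples at 10 Hz; None -> task default
    pulses: list[tuple[float, float, float]] | None = None  # None -> task default
    noise_sd: float = 0.01  # g
    trial_jitter: float = 0.05  # fractional time/amplitude variability
    rest_len: int = 15  # rest baseline between trials, samples
    seed: int = 0

    def resolved(self) -> "MotionParams":
        out = self
        if out.trial_len is None:
            out = replace(out, trial_len=_TRIAL_LEN[self.task])
        if out.pulses is None:
            out = replace(out, pulses=list(_TASK_PULSES[self.task]))
        return out


@dataclass
class SyntheticPair:
    """Two curves congruent only inside a known index range."""

    left: RepresentativeCurve
    right: RepresentativeCurve
    truth: tuple[int, int]  # inclusive index range of planted congruence
    transform: tuple[float, np.ndarray, np.ndarray]  # (scale, rotation, translation)


@dataclass
class SubjectRecord:
    """One simulated subject: six streams per task plus ground truth."""

    subject_id: str
    group: int
    age: float
    arm_length: float
    eye_height: float
    streams: dict[str, dict[Placement, SensorStream]]
    truth: dict[str, dict] = field(default_factory=dict)


def task_pulses(task: str, side: str = "right") -> list[tuple[float, float, float]]:
    """Default pulse layout for a task; the cabinet task is asymmetric."""
    if task == "cabinet" and side == "left":
        return list(_TASK_PULSES["cabinet_nondominant"])
    return list(_TASK_PULSES[task])


def _quantize(arr: np.ndarray, step: float) -> np.ndarray:
    return np.round(arr / step) * step


def _pulse_profile(
    n: int, pulses, amp_scale: float = 1.0, envelope: float = 0.0
) -> np.ndarray:
    t = np.arange(n) / max(n - 1, 1)
    y = np.zeros(n)
    for center, width, amp in pulses:
        if not 0.0 <= center < 1.0 + 1e-9:
            raise ValueError(f"pulse center {center} outside the trial")
        y += amp_scale * amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    if envelope:
        y += amp_scale * envelope * np.exp(-0.5 * ((t - 0.5) / 0.35) ** 2)
    return y


def characteristic_peaks(y: np.ndarray) -> int:
    """Count a profile's characteristic peaks: local maxima reaching at
    least half the profile maximum, with non-trivial prominence."""
    from scipy.signal import find_peaks

    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        return 0
    peaks, _ = find_peaks(y, height=0.5 * y.max(), prominence=0.05 * np.ptp(y))
    return int(peaks.size)


def make_task_curve(params: MotionParams) -> np.ndarray:
    """One trial's N x 3 acceleration curve for the task's pulse layout.

    The y axis carries the pulse-sum profile; x and z carry small
    correlated components (a scaled, shifted copy of y).  Deterministic
    for a given seed; values quantized to the 0.005 g sensor grid.
    """
    p = params.resolved()
    rng = np.random.default_rng(p.seed)
    n = p.trial_len
    y = _pulse_profile(n, p.pulses, envelope=_TASK_ENVELOPE.get(p.task, 0.0))
    x = 0.25 * np.roll(y, max(1, n // 20)) + rng.normal(0, p.noise_sd, n)
    z = -0.15 * np.roll(y, -max(1, n // 20)) + rng.normal(0, p.noise_sd, n)
    y = y + rng.normal(0, p.noise_sd, n)
    curve = np.column_stack([x, y, z])
    return _quantize(curve, ACCEL_RESOLUTION_G)


def _smooth_noise_curve(n: int, rng: np.random.Generator, scale: float = 0.4) -> np.ndarray:
    """Independent smooth 3-axis signal: a dense train of random Gaussian
    lobes per axis, structured enough that two independent draws are not
    congruent under a similarity transform."""
    out = np.zeros((n, 3))
    t = np.arange(n) / max(n - 1, 1)
    for j in range(3):
        for _ in range(rng.integers(8, 14)):
            c = rng.uniform(0, 1)
            w = rng.uniform(0.02, 0.06)
            a = rng.uniform(-scale, scale)
            out[:, j] += a * np.exp(-0.5 * ((t - c) / w) ** 2)
    return out


def plant_congruent_pair(
    base: np.ndarray,
    truth: tuple[int, int],
    transform: tuple[float, np.ndarray, np.ndarray] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    min_window: int = 2,
) -> SyntheticPair:
    """Build a curve pair congruent exactly on ``truth`` (inclusive).

    Inside the range the second curve is ``scale * base @ rotation +
    translation`` plus Gaussian noise; outside it is an independent smooth
    signal from a re-seeded generator.
    """
    base = np.asarray(base, dtype=float)
    n = base.shape[0]
    lo, hi = truth
    if not (0 <= lo <= hi < n):
        raise ValueError("truth range outside the curve")
    if hi - lo + 1 < min_window:
        raise ValueError("truth range shorter than the expanding window")
    rng = np.random.default_rng(seed)
    if transform is None:
        theta = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        transform = (float(rng.uniform(0.5, 2.0)), rot, rng.uniform(-0.5, 0.5, 3))
    scale, rot, shift = transform
    if scale <= 0:
        raise ValueError("scale must be positive")

    other = _smooth_noise_curve(n, rng)
    inside = scale * base[lo : hi + 1] @ rot + shift
    inside = inside + rng.normal(0, noise_sd, inside.shape)
    other[lo : hi + 1] = inside
    return SyntheticPair(
        left=RepresentativeCurve(values=other, n_trials=1),
        right=RepresentativeCurve(values=base.copy(), n_trials=1),
        truth=(lo, hi),
        transform=(scale, rot, np.asarray(shift, dtype=float)),
    )


def _stream_from_accel(
    accel: np.ndarray, placement: Placement, rate: float = 10.0
) -> SensorStream:
    """Wrap an acceleration signal with derived gyro/angle channels.

    Gyro is a scaled copy of the acceleration profile and the Euler angles
    its smoothed cumulative trace -- crude but sufficient surrogates for
    the kinematic feature extraction, quantized to the sensor grids.
    """
    n = accel.shape[0]
    t = np.arange(n) / rate
    gyro = _quantize(200.0 * accel, GYRO_RESOLUTION_DPS)  # deg/s per g, heuristic
    ang = np.cumsum(accel, axis=0) / rate * 20.0
    ang = _quantize(np.clip(ang, -180, 180), ANGLE_RESOLUTION_DEG)
    data = pd.DataFrame(
        {
            "t": t,
            "ax": accel[:, 0],
            "ay": accel[:, 1],
            "az": accel[:, 2],
            "gx": gyro[:, 0],
            "gy": gyro[:, 1],
            "gz": gyro[:, 2],
            "roll": ang[:, 1],  # roll = rotation about the forward y axis
            "pitch": ang[:, 0],
            "yaw": ang[:, 2],
        }
    )
    return SensorStream(placement=placement, data=data, nominal_rate=rate)


#: per-segment amplitude scaling: hands move more than upper arms
_SEGMENT_GAIN = {"upper_arm": 1.0, "forearm": 1.35, "hand": 1.7}


def simulate_subject(
    task: str,
    params: MotionParams | None = None,
    seed: int = 0,
    subject_id: str = "SIM.01",
    group: int = 1,
    coordinated_segments: tuple[str, ...] = ("upper_arm", "forearm", "hand"),
) -> SubjectRecord:
    """Simulate one subject's six placements for one task.

    Ten jittered trial repetitions are concatenated with rest baselines so
    the boundary rules can recover them.  Left-side streams of
    ``coordinated_segments`` replay the right side's trial shapes (the
    bilateral coordination the study looks for); other left segments get
    independently shaped trials.  For the asymmetric cabinet task the left
    side always uses the two-pulse non-dominant layout.  Ground truth
    (trial boundaries) is attached.
    """
    if params is None:
        params = MotionParams(task=task, seed=seed)
    p = params.resolved()
    rng = np.random.default_rng(seed)

    # per-trial jitter schedule shared by all placements so that streams
    # stay sample-aligned
    lens = np.maximum(
        5, np.round(p.trial_len * (1 + rng.normal(0, p.trial_jitter, p.n_trials))).astype(int)
    )
    rests = np.maximum(
        3, np.round(p.rest_len * (1 + rng.normal(0, p.trial_jitter, p.n_trials + 1))).astype(int)
    )
    amps = 1 + rng.normal(0, p.trial_jitter, p.n_trials)

    streams: dict[Placement, SensorStream] = {}
    boundaries: list[tuple[int, int]] = []
    for pl_idx, placement in enumerate(all_placements()):
        if task == "cabinet":
            pulses = task_pulses(task, placement.side)
        else:
            pulses = list(p.pulses)
        mirrored = (
            placement.side == "left"
            and task != "cabinet"
            and placement.segment not in coordinated_segments
        )
        gain = _SEGMENT_GAIN[placement.segment]
        pieces = []
        marks = []
        pos = 0
        for k in range(p.n_trials):
            # independent but reproducible noise per (placement, trial)
            noise_rng = np.random.default_rng((seed, pl_idx, k))
            r = int(rests[k])
            pieces.append(noise_rng.normal(0, p.noise_sd / 2, (r, 3)))
            pos += r
            n_k = int(lens[k])
            if mirrored:
                # uncoordinated: an independent movement per trial, so the
                # trial average carries no coherent shape shared with the
                # contralateral side
                trial = gain * _smooth_noise_curve(n_k, noise_rng, scale=0.4)
                trial += noise_rng.normal(0, p.noise_sd, (n_k, 3))
            else:
                y = _pulse_profile(
                    n_k,
                    pulses,
                    amp_scale=gain * amps[k],
                    envelope=_TASK_ENVELOPE.get(task, 0.0),
                )
                x = 0.25 * np.roll(y, max(1, n_k // 20))
                z = -0.15 * np.roll(y, -max(1, n_k // 20))
                trial = np.column_stack([x, y, z]) + noise_rng.normal(
                    0, p.noise_sd, (n_k, 3)
                )
            pieces.append(trial)
            marks.append((pos, pos + n_k))
            pos += n_k
        pieces.append(np.zeros((int(rests[-1]), 3)))
        accel = _quantize(np.concatenate(pieces), ACCEL_RESOLUTION_G)
        streams[placement] = _stream_from_accel(accel, placement)
        boundaries = marks  # identical for every placement by construction

    demo = {"group": group, "age": 25.0 if group == 1 else 56.0}
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        age=demo["age"],
        arm_length=73.0,
        eye_height=148.0,
        streams={task: streams},
        truth={task: {"trial_boundaries": boundaries}},
    )
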
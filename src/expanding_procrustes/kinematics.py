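"""Per-placement kinematic features.

All features follow the forward-movement convention: the sensors are
mounted so the positive y-axis points along the reaching direction, and
angular velocity / roll angle are read from the y channels only.  Peak
velocities are reported as the maximum and the absolute value of the
minimum; peak roll angles keep their sign (limbs can roll either way).
Durations come from the raw trial segments, before any resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Placement, SensorStream
from .segmentation import (
    RepresentativeCurve,
    TaskSpec,
    TrialSegment,
    average_trials,
    trial_duration,
)

__all__ = [
    "KinematicSummary",
    "peak_angular_velocity",
    "peak_roll_angle",
    "summarize_placements",
    "summary_frame",
]


@dataclass
class KinematicSummary:
    placement: Placement
    vel_max: float
    vel_min_abs: float
    roll_max: float
    roll_min: float
    duration_mean: float


def peak_angular_velocity(gyro_y: np.ndarray) -> tuple[float, float]:
    """(maximum, |minimum|) of the forward-axis angular velocity in deg/s."""
    arr = np.asarray(gyro_y, dtype=float)
    if arr.size == 0:
        raise ValueError("empty angular-velocity series")
    return float(arr.max()), float(abs(arr.min()))


def peak_roll_angle(roll: np.ndarray) -> tuple[float, float]:
    """(signed maximum, signed minimum) roll angle in degrees."""
    arr = np.asarray(roll, dtype=float)
    if arr.size == 0:
        raise ValueError("empty roll-angle series")
    return float(arr.max()), float(arr.min())


def _representative_channel(
    stream: SensorStream, segments: list[TrialSegment], channel: str, N: int
) -> np.ndarray:
    series = stream.channel(channel)
    trials = [series[seg.start : seg.end, None] for seg in segments]
    return average_trials(trials, N=N).values[:, 0]


def summarize_placements(
    streams: dict[Placement, SensorStream],
    segments: list[TrialSegment],
    rate: float = 10.0,
) -> list[KinematicSummary]:
    """One kinematic summary per placement.

    Velocity and roll peaks are computed on the trial-averaged
    representative curves of the y channels; mean duration comes from the
    raw segment lengths.
    """
    if not segments:
        raise ValueError("no trial segments; cannot summarize")
    N = max(2, int(round(float(np.mean([s.length for s in segments])))))
    dur = float(np.mean([trial_duration(s, rate) for s in segments]))
    out = []
    for placement, stream in streams.items():
        gy = _representative_channel(stream, segments, "gy", N)
        roll = _representative_channel(stream, segments, "roll", N)
        vmax, vmin = peak_angular_velocity(gy)
        rmax, rmin = peak_roll_angle(roll)
        out.append(
            KinematicSummary(
                placement=placement,
                vel_max=vmax,
                vel_min_abs=vmin,
                roll_max=rmax,
                roll_min=rmin,
                duration_mean=dur,
            )
        )
    return out


def summary_frame(summaries: list[KinematicSummary], subject: str = "", task: str = "") -> pd.DataFrame:
    """Delimited-report form: one row per (subject, task, placement)."""
    return pd.DataFrame(
        [
            {
                "subject": subject,
                "task": task,
                "placement": str(s.placement),
                "vel_max_dps": s.vel_max,
                "vel_min_abs_dps": s.vel_min_abs,
                "roll_max_deg": s.roll_max,
                "roll_min_deg": s.roll_min,
                "duration_mean_s": s.duration_mean,
            }
            for s in summaries
        ]
    )
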
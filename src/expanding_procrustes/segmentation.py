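"""Dropout repair, trial-boundary detection and representative curves.

Recordings are segmented on the right-upper-arm forward (positive y)
acceleration.  Each task has its own boundary rule:

* ``reach``   -- a trial is a local maximum preceded and followed by the
  minimum value of acceleration (neutral position): min - max - min.
* ``button`` / ``unbutton`` -- a trial spans a local minimum to the next
  local maximum (neutral position to highest button).
* ``cabinet`` -- a trial spans two consecutive local minima (arms by the
  sides before and after the reach).

Extrema are the series' local maxima filtered by prominence (default 10%
of the series range) and a minimum separation.  Boundary minima are the
acceleration minima between consecutive qualifying maxima (and in the
flanking regions) that return close to the series minimum -- the neutral
position -- which keeps the rules well-posed on flat rest baselines and
prevents the within-trial pulse structure (two reach pulses, four button
pulses) from being over-segmented: during continuous movement the
acceleration dips between pulses stay elevated, while between trials it
rests at the neutral level.  The index windows found on the reference
stream are applied
unchanged to all six placements, guaranteeing the equal-length pairs the
expanding algorithm requires, and the per-placement trials are resampled
to a common length and averaged point-wise into representative curves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io import CHANNELS, Placement, SensorStream

__all__ = [
    "TaskSpec",
    "TrialSegment",
    "RepresentativeCurve",
    "RepairError",
    "AlignmentError",
    "fill_dropouts",
    "detect_trials",
    "apply_boundaries",
    "resample_trial",
    "average_trials",
    "trial_duration",
    "representative_curves",
]

logger = logging.getLogger(__name__)

TASKS = ("reach", "button", "unbutton", "cabinet")

#: boundary rule fixed by task
BOUNDARY_RULES = {
    "reach": "min-max-min",
    "button": "min-next-max",
    "unbutton": "min-next-max",
    "cabinet": "min-next-min",
}

#: fraction of the series range above its minimum within which a local
#: minimum counts as a return to the neutral position (a trial boundary)
DEFAULT_DEPTH_FRAC = 0.15


class RepairError(ValueError):
    """A channel cannot be repaired (entirely missing)."""


class AlignmentError(ValueError):
    """Streams are not sample-aligned with the segmentation reference."""


@dataclass
class TaskSpec:
    """Boundary rule and extremum-detection parameters for one task."""

    task: str
    min_prominence: float | None = None  # absolute; None -> prominence_frac * range
    min_separation: int = 5
    prominence_frac: float = 0.10
    depth_frac: float = DEFAULT_DEPTH_FRAC

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")

    @property
    def boundary_rule(self) -> str:
        return BOUNDARY_RULES[self.task]

    @classmethod
    def for_task(cls, task: str) -> "TaskSpec":
        """Default detection parameters for one of the study tasks."""
        return cls(task=task)


@dataclass
class TrialSegment:
    """Half-open sample window [start, end) of one trial, 0-based."""

    start: int
    end: int
    trial_no: int
    landmarks: tuple[int, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RepresentativeCurve:
    """Trial-averaged N x 3 acceleration trajectory for one placement."""

    values: np.ndarray
    n_trials: int
    placement: Placement | None = None
    task: str | None = None

    @property
    def N(self) -> int:
        return self.values.shape[0]

    def axis(self, i: int) -> np.ndarray:
        return self.values[:, i]


def fill_dropouts(stream: SensorStream) -> SensorStream:
    """Repair missing samples channel-wise.

    Interior runs of missing values are linearly interpolated between the
    flanking observed values; leading/trailing runs take the nearest
    observed value (one-sided interpolation is undefined).  A channel with
    no observed values at all is an error.
    """
    data = stream.data.copy()
    t = data["t"].to_numpy(float)
    for ch in CHANNELS:
        y = data[ch].to_numpy(float)
        ok = np.isfinite(y)
        if ok.all():
            continue
        if ok.sum() < 2:
            if ok.sum() == 0:
                raise RepairError(f"channel {ch!r} is entirely missing")
            data[ch] = y[ok][0]
            continue
        # np.interp clamps to the nearest observed value outside the range
        data[ch] = np.interp(t, t[ok], y[ok])
    return SensorStream(
        placement=stream.placement, data=data, nominal_rate=stream.nominal_rate
    )


def _qualifying_maxima(y: np.ndarray, spec: TaskSpec) -> np.ndarray:
    rng = float(np.ptp(y))
    if rng == 0.0:
        return np.array([], dtype=int)
    prom = spec.min_prominence
    if prom is None:
        prom = spec.prominence_frac * rng
    peaks, _ = find_peaks(y, prominence=prom, distance=spec.min_separation)
    return peaks


def _boundary_minima(y: np.ndarray, maxima: np.ndarray, depth_frac: float) -> np.ndarray:
    """Neutral-position minima: the acceleration minimum between each pair
    of consecutive maxima (and in the flanking regions), kept only when it
    returns within ``depth_frac`` of the series range above the series
    minimum.  Depth is measured relative to the range, so the result is
    invariant to constant offsets."""
    edges = [0, *maxima.tolist(), y.size - 1]
    deep_level = y.min() + depth_frac * np.ptp(y)
    minima = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        if hi > lo:
            m = lo + int(np.argmin(y[lo : hi + 1]))
            if y[m] <= deep_level:
                minima.append(m)
    return np.unique(np.asarray(minima, dtype=int))


def detect_trials(y_accel: np.ndarray, spec: TaskSpec) -> list[TrialSegment]:
    """Detect trial boundaries on a 1-D forward-acceleration series.

    Returns ordered, non-overlapping segments per the task's boundary
    rule: a trial runs between two consecutive neutral-position minima
    (reach requires an intervening maximum; the cabinet rule takes the
    span as-is), or from a neutral minimum to the last maximum before the
    next one (buttoning: neutral position to the highest button).
    Detection depends only on the series' shape (prominence), not its
    absolute level.  If no qualifying extrema exist an empty list is
    returned and a warning logged.
    """
    y = np.asarray(y_accel, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("series must be 1-D with at least 3 samples")
    maxima = _qualifying_maxima(y, spec)
    if maxima.size == 0:
        logger.warning("no qualifying extrema found; returning no trials")
        return []
    minima = _boundary_minima(y, maxima, spec.depth_frac)

    segments: list[TrialSegment] = []
    for lo, hi in zip(minima[:-1], minima[1:]):
        inside = maxima[(maxima > lo) & (maxima < hi)]
        if inside.size == 0:
            continue
        lo, hi = int(lo), int(hi)
        if spec.boundary_rule == "min-next-max":
            peak = int(inside[-1])
            seg = TrialSegment(lo, peak + 1, 0, landmarks=(lo, peak))
        else:  # min-max-min and min-next-min: between consecutive minima
            peak = int(inside[np.argmax(y[inside])])
            seg = TrialSegment(lo, hi, 0, landmarks=(lo, peak, hi))
        if seg.length >= spec.min_separation:
            segments.append(seg)

    for i, seg in enumerate(segments):
        seg.trial_no = i + 1
    if not segments:
        logger.warning("extrema found but no segment satisfied the rule")
    return segments


def apply_boundaries(
    streams: dict[Placement, SensorStream], segments: list[TrialSegment]
) -> dict[Placement, list[np.ndarray]]:
    """Slice identical index windows from every placement's acceleration.

    All streams must be sample-aligned (equal length) with the reference
    used for detection; the result maps each placement to one k x 3 trial
    curve per segment, with lengths equal across placements.
    """
    lengths = {str(p): len(s) for p, s in streams.items()}
    if len(set(lengths.values())) > 1:
        raise AlignmentError(f"stream lengths differ across placements: {lengths}")
    n = next(iter(lengths.values())) if lengths else 0
    for seg in segments:
        if seg.end > n:
            raise AlignmentError(
                f"segment [{seg.start}, {seg.end}) exceeds stream length {n}"
            )
    return {
        placement: [stream.accel()[seg.start : seg.end] for seg in segments]
        for placement, stream in streams.items()
    }


def resample_trial(curve: np.ndarray, N: int) -> np.ndarray:
    """Per-axis linear interpolation onto N equispaced points over the
    trial's normalized time [0, 1]; endpoints are preserved exactly."""
    curve = np.asarray(curve, dtype=float)
    if curve.ndim != 2 or curve.shape[0] < 2:
        raise ValueError("curve must be k x d with k >= 2")
    if N < 2:
        raise ValueError("target length N must be >= 2")
    k = curve.shape[0]
    if N == k:
        return curve.copy()
    src = np.linspace(0.0, 1.0, k)
    dst = np.linspace(0.0, 1.0, N)
    return np.column_stack([np.interp(dst, src, curve[:, j]) for j in range(curve.shape[1])])


def average_trials(
    trials: list[np.ndarray],
    N: int | None = None,
    placement: Placement | None = None,
    task: str | None = None,
) -> RepresentativeCurve:
    """Resample every trial to a common length and average point-wise.

    ``N`` defaults to the rounded mean trial length, preserving the 10 Hz
    temporal scale on average.
    """
    if not trials:
        raise ValueError("need at least one trial to average")
    if N is None:
        N = int(round(float(np.mean([t.shape[0] for t in trials]))))
        N = max(N, 2)
    stacked = np.stack([resample_trial(t, N) for t in trials])
    return RepresentativeCurve(
        values=stacked.mean(axis=0), n_trials=len(trials), placement=placement, task=task
    )


def trial_duration(segment: TrialSegment, rate: float = 10.0) -> float:
    """Trial duration in seconds at the given sampling rate."""
    if rate <= 0:
        raise ValueError("rate must be positive")
    return segment.length / rate


def representative_curves(
    streams: dict[Placement, SensorStream],
    segments: list[TrialSegment],
    N: int | None = None,
    task: str | None = None,
) -> dict[Placement, RepresentativeCurve]:
    """Segment every placement and average its trials; all returned curves
    share the same N (rounded mean trial length unless given)."""
    trial_sets = apply_boundaries(streams, segments)
    if N is None and segments:
        N = max(2, int(round(float(np.mean([seg.length for seg in segments])))))
    return {
        placement: average_trials(trials, N=N, placement=placement, task=task)
        for placement, trials in trial_sets.items()
    }
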
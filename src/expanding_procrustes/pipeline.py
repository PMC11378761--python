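"""End-to-end orchestration: segment, average, coordinate, report.

Inter-limb analysis compares homologous segments across the body midline
(right upper arm vs left upper arm, etc.) with the right limb as the
Procrustes reference (subjects are right-hand dominant).  Intra-limb
analysis compares segment pairs within one arm (upper arm-forearm,
upper arm-hand, forearm-hand) with the more proximal segment as the
reference, and applies the temporal gate by default: a spatially
congruent interval that falls entirely outside the movement stages of the
task does not count as coordination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .expanding import CoordinationResult, coordinate_pair
from .io import Placement, SensorStream
from .segmentation import (
    RepresentativeCurve,
    TaskSpec,
    detect_trials,
    fill_dropouts,
    representative_curves,
)
from .synthetic import SubjectRecord

__all__ = [
    "AggregationError",
    "segment_record",
    "movement_stages",
    "run_interlimb",
    "run_intralimb",
    "results_frame",
]

logger = logging.getLogger(__name__)

#: reference placement for segmentation: right upper arm, forward (y) axis
REFERENCE_PLACEMENT = Placement("right", "upper_arm")

#: intra-limb pairs, proximal segment first (used as reference X)
INTRA_PAIRS = (("upper_arm", "forearm"), ("upper_arm", "hand"), ("forearm", "hand"))


class AggregationError(KeyError):
    """A required stream is missing from the record."""


def segment_record(
    record: SubjectRecord, task: str, config: RunConfig | None = None
) -> dict[Placement, RepresentativeCurve]:
    """Repair, segment on the right-upper-arm forward acceleration, and
    average each placement's trials into a representative curve."""
    config = config or RunConfig()
    try:
        streams = record.streams[task]
    except KeyError as exc:
        raise AggregationError(f"record has no streams for task {task!r}") from exc
    if REFERENCE_PLACEMENT not in streams:
        raise AggregationError("record lacks the right-upper-arm reference stream")

    repaired = {pl: fill_dropouts(s) for pl, s in streams.items()}
    spec = TaskSpec.for_task(task)
    spec.prominence_frac = config.prominence_frac
    segments = detect_trials(repaired[REFERENCE_PLACEMENT].channel("ay"), spec)
    logger.info("task %s: %d trials detected", task, len(segments))
    if not segments:
        raise AggregationError(f"no trials detected for task {task!r}")
    return representative_curves(repaired, segments, N=config.fixed_length, task=task)


def movement_stages(
    reference_y: np.ndarray, threshold_frac: float = 0.10
) -> list[tuple[int, int]]:
    """Task stages on a representative curve: contiguous runs where the
    forward acceleration magnitude exceeds a fraction of its peak."""
    y = np.abs(np.asarray(reference_y, dtype=float))
    if y.size == 0:
        return []
    mask = y >= threshold_frac * y.max()
    stages = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            stages.append((start, i - 1))
            start = None
    if start is not None:
        stages.append((start, y.size - 1))
    return stages


def _require(curves: dict[Placement, RepresentativeCurve], placement: Placement):
    if placement not in curves:
        raise AggregationError(f"missing stream for placement {placement}")
    return curves[placement].values


def run_interlimb(
    curves: dict[Placement, RepresentativeCurve],
    config: RunConfig | None = None,
) -> list[CoordinationResult]:
    """Expanding-Procrustes coordination of the three homologous pairs.

    The right-side curve is the reference X of each pair; no temporal
    gate is applied (the pairs already share the task timeline).
    """
    config = config or RunConfig()
    results = []
    for segment in ("upper_arm", "forearm", "hand"):
        right = _require(curves, Placement("right", segment))
        left = _require(curves, Placement("left", segment))
        results.append(
            coordinate_pair(
                right,
                left,
                pair=(f"right_{segment}", f"left_{segment}"),
                tau=config.tau,
                w_frac=config.window_frac,
                allow_reflection=config.allow_reflection,
                epsilon=config.epsilon,
            )
        )
    return results


def run_intralimb(
    curves: dict[Placement, RepresentativeCurve],
    side: str = "right",
    config: RunConfig | None = None,
    gate_stages: bool = True,
) -> list[CoordinationResult]:
    """Within-arm coordination of the three segment pairs on one side.

    With ``gate_stages`` (the default) congruent intervals must overlap a
    movement stage of the arm's own forward-acceleration profile.
    """
    config = config or RunConfig()
    stages = None
    if gate_stages:
        ref = _require(curves, Placement(side, "upper_arm"))
        stages = movement_stages(ref[:, 1])
    results = []
    for prox, dist in INTRA_PAIRS:
        X = _require(curves, Placement(side, prox))
        Y = _require(curves, Placement(side, dist))
        results.append(
            coordinate_pair(
                X,
                Y,
                pair=(f"{side}_{prox}", f"{side}_{dist}"),
                tau=config.tau,
                w_frac=config.window_frac,
                stage_windows=stages,
                allow_reflection=config.allow_reflection,
                epsilon=config.epsilon,
            )
        )
    return results


def results_frame(
    results: list[CoordinationResult], subject: str = "", task: str = ""
) -> pd.DataFrame:
    """Delimited-report form: one row per analyzed pair."""
    rows = []
    for r in results:
        rows.append(
            {
                "subject": subject,
                "task": task,
                "pair": "~".join(r.pair),
                "min_idx": None if r.interval.empty else r.interval.min_idx,
                "max_idx": None if r.interval.empty else r.interval.max_idx,
                "di": r.di,
                "percent_similarity": r.percent_similarity,
                "score": r.score,
                "log_score": r.log_score,
            }
        )
    return pd.DataFrame(rows)
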
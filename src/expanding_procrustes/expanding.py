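"""The Expanding Procrustes algorithm.

Given two equal-length trajectories (typically the trial-averaged
acceleration curves of homologous limb segments), the algorithm localizes
in time the most congruent sub-segment:

1. *Scan*: a sliding window sized to a fraction of the curve (default 10%)
   traverses both curves in lockstep; the Procrustes dissimilarity of each
   windowed pair is recorded.
2. *Seed*: the window with the lowest dissimilarity marks the region of
   highest spatial congruence.
3. *Expand*: if the seed dissimilarity is below the threshold tau (default
   0.15), the segment is grown forward one sample at a time -- re-fitting
   the full Procrustes superimposition on the grown segment after every
   step -- for as long as the dissimilarity stays below tau, then grown
   backward the same way.  A seed above tau yields the empty interval,
   reported downstream as 0% similarity.

The localized interval's length, as a percentage of the whole curve, is
the percent similarity; percent divided by the interval's dissimilarity is
the coordination score, which is log-normalized (ln(1 + x)) before group
statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .procrustes import DegenerateInputError, dissimilarity

__all__ = [
    "DEFAULT_TAU",
    "DEFAULT_WINDOW_FRAC",
    "ScanProfile",
    "CongruenceInterval",
    "CoordinationResult",
    "window_length",
    "scan",
    "select_seed",
    "expand",
    "percent_similarity",
    "coordination_score",
    "log_normalize",
    "temporal_gate",
    "coordinate_pair",
]

#: dissimilarity threshold: the average dissimilarity between stages of a
#: simple reaching task in the calibration data set this method inherits
DEFAULT_TAU = 0.15
#: sliding window as a fraction of the whole movement curve
DEFAULT_WINDOW_FRAC = 0.10
#: floor protecting the percent/DI ratio when DI underflows to zero
DEFAULT_EPSILON = 1e-6


@dataclass
class ScanProfile:
    """Dissimilarity of every window start during the sliding-window scan."""

    w: int
    di: np.ndarray  # length N - w + 1, values in [0, 1]

    @property
    def starts(self) -> np.ndarray:
        return np.arange(self.di.size)


@dataclass
class CongruenceInterval:
    """Inclusive temporal indices of the localized congruent segment."""

    min_idx: int = 0
    max_idx: int = -1
    di: float = 1.0
    seed_start: int = -1
    empty: bool = True

    @property
    def length(self) -> int:
        return 0 if self.empty else self.max_idx - self.min_idx + 1


@dataclass
class CoordinationResult:
    """Percent similarity, dissimilarity and coordination score for one pair."""

    pair: tuple[str, str]
    interval: CongruenceInterval
    percent_similarity: float
    di: float
    score: float
    log_score: float


def window_length(n: int, w_frac: float = DEFAULT_WINDOW_FRAC) -> int:
    """Window size: round(w_frac * N), clamped to at least 2 samples."""
    return max(2, int(round(w_frac * n)))


def scan(
    X: np.ndarray,
    Y: np.ndarray,
    w_frac: float = DEFAULT_WINDOW_FRAC,
    allow_reflection: bool = True,
) -> ScanProfile:
    """Slide a window of 10% (by default) of the curve over both curves and
    record the Procrustes dissimilarity at every start (step 1 sample).

    A window where the reference has zero spatial variance is recorded as
    fully dissimilar (di = 1) with a warning.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"curves must have equal shape: {X.shape} vs {Y.shape}")
    n = X.shape[0]
    w = window_length(n, w_frac)
    if n < w:
        raise ValueError(f"curve length {n} shorter than window {w}")
    di = np.empty(n - w + 1)
    for s in range(n - w + 1):
        try:
            di[s] = dissimilarity(
                X[s : s + w], Y[s : s + w], allow_reflection=allow_reflection
            )
        except DegenerateInputError:
            warnings.warn(f"zero-variance window at start {s}; recording di = 1")
            di[s] = 1.0
    return ScanProfile(w=w, di=di)


def select_seed(profile: ScanProfile) -> int:
    """Start index of the minimum-dissimilarity window (earliest on ties)."""
    if profile.di.size == 0:
        raise ValueError("empty scan profile")
    return int(np.argmin(profile.di))


def _segment_di(
    X: np.ndarray, Y: np.ndarray, lo: int, hi: int, allow_reflection: bool
) -> float:
    """Dissimilarity of the inclusive segment [lo, hi]; degenerate -> 1."""
    try:
        return dissimilarity(
            X[lo : hi + 1], Y[lo : hi + 1], allow_reflection=allow_reflection
        )
    except DegenerateInputError:
        return 1.0


def expand(
    X: np.ndarray,
    Y: np.ndarray,
    seed_start: int,
    tau: float = DEFAULT_TAU,
    w_frac: float = DEFAULT_WINDOW_FRAC,
    allow_reflection: bool = True,
) -> CongruenceInterval:
    """Grow the seed window into the maximal congruent interval.

    The right edge advances one sample at a time while the full-segment
    dissimilarity stays at or below ``tau``; after the maximum time index
    is fixed, the left edge retreats the same way.  If the seed window
    itself exceeds ``tau`` the result is the empty interval.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("curves must have equal shape")
    n = X.shape[0]
    w = window_length(n, w_frac)
    if not 0 <= seed_start <= n - w:
        raise ValueError(f"seed start {seed_start} invalid for N={n}, w={w}")
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must lie in (0, 1)")

    lo, hi = seed_start, seed_start + w - 1
    di = _segment_di(X, Y, lo, hi, allow_reflection)
    if di > tau:
        return CongruenceInterval(seed_start=seed_start, empty=True)

    # Forward fully, then backward; repeated until neither edge can move so
    # the result is locally maximal (any one-sample extension exceeds tau).
    grew = True
    while grew:
        grew = False
        while hi + 1 < n:
            trial = _segment_di(X, Y, lo, hi + 1, allow_reflection)
            if trial > tau:
                break
            hi += 1
            di = trial
            grew = True
        while lo - 1 >= 0:
            trial = _segment_di(X, Y, lo - 1, hi, allow_reflection)
            if trial > tau:
                break
            lo -= 1
            di = trial
            grew = True
    return CongruenceInterval(
        min_idx=lo, max_idx=hi, di=di, seed_start=seed_start, empty=False
    )


def percent_similarity(interval: CongruenceInterval, n: int) -> float:
    """Length of the congruent interval as a percentage of the whole curve."""
    if interval.empty:
        return 0.0
    return 100.0 * interval.length / n


def coordination_score(
    percent: float, di: float, epsilon: float = DEFAULT_EPSILON
) -> float:
    """Percent similarity divided by the dissimilarity index.

    High similarity and low dissimilarity both push the score up.  A zero
    percent (no congruent interval) scores 0 regardless of di; a di of
    exactly 0 is floored at ``epsilon`` so a fully congruent pair saturates
    rather than dividing by zero.
    """
    if percent == 0.0:
        return 0.0
    return percent / max(di, epsilon)


def log_normalize(scores) -> np.ndarray:
    """Order-preserving logarithmic normalization, ln(1 + score); 0 -> 0."""
    arr = np.asarray(scores, dtype=float)
    if np.any(arr < 0):
        raise ValueError("coordination scores must be non-negative")
    return np.log1p(arr)


def temporal_gate(
    interval: CongruenceInterval, stage_windows: list[tuple[int, int]]
) -> CongruenceInterval:
    """Zero out intervals that do not coincide with any task stage.

    Congruent shapes that do not match temporally to task-specific stages
    of movement are not counted as coordination: the interval is kept only
    if it overlaps at least one stage window (inclusive ranges) by at
    least one sample.
    """
    if interval.empty:
        return interval
    for lo, hi in stage_windows:
        if interval.min_idx <= hi and interval.max_idx >= lo:
            return interval
    return CongruenceInterval(seed_start=interval.seed_start, empty=True)


def coordinate_pair(
    X: np.ndarray,
    Y: np.ndarray,
    pair: tuple[str, str] = ("X", "Y"),
    tau: float = DEFAULT_TAU,
    w_frac: float = DEFAULT_WINDOW_FRAC,
    stage_windows: list[tuple[int, int]] | None = None,
    allow_reflection: bool = True,
    epsilon: float = DEFAULT_EPSILON,
) -> CoordinationResult:
    """Full scan -> seed -> expand -> score pipeline for one curve pair.

    ``stage_windows`` (if given) applies the intra-limb temporal gate
    before scoring.
    """
    profile = scan(X, Y, w_frac=w_frac, allow_reflection=allow_reflection)
    seed = select_seed(profile)
    interval = expand(
        X, Y, seed, tau=tau, w_frac=w_frac, allow_reflection=allow_reflection
    )
    if stage_windows is not None:
        interval = temporal_gate(interval, stage_windows)
    pct = percent_similarity(interval, X.shape[0])
    di = interval.di if not interval.empty else float(profile.di[seed])
    score = coordination_score(pct, di, epsilon=epsilon)
    return CoordinationResult(
        pair=pair,
        interval=interval,
        percent_similarity=pct,
        di=di,
        score=score,
        log_score=float(np.log1p(score)),
    )
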
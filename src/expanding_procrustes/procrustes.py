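"""Traditional Procrustes superimposition for equal-length trajectories.

A trajectory is a k x d point set (d = 2 or 3; here usually a 3-axis
acceleration curve indexed by time).  Conforming a curve Y to a reference
curve X means finding the similarity transform -- translation c, positive
scale b, and orthogonal matrix T (rotation, or rotation/reflection) --
whose application to Y minimizes the summed squared distance to X:

    Z = b * (Y - mean(Y)) * T + c,   c = mean(X).

The dissimilarity index D standardizes the residual by the total sum of
squares of the centered reference,

    D = ||Xc - b * Yc * T||^2 / ||Xc||^2,

so that D = 0 at complete congruence (Y is an exact similarity transform
of X) and D <= 1 whenever the scale is optimized: the statistic reduces to
1 - (trace Sigma)^2 / (||Xc||^2 ||Yc||^2) with Sigma the singular values of
Yc' Xc, a squared-cosine complement that cannot exceed one.  D is
normalized by X and is not symmetric in its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import svd

__all__ = [
    "DegenerateInputError",
    "AlignmentResult",
    "center",
    "rmsd_scale",
    "optimal_rotation",
    "conform",
    "dissimilarity",
]


class DegenerateInputError(ValueError):
    """A point set with fewer than two points or zero spatial variance."""


@dataclass
class AlignmentResult:
    """Optimal similarity transform of Y onto X and its standardized residual."""

    b: float
    T: np.ndarray
    c: np.ndarray
    Z: np.ndarray
    D: float


def _as_pointset(points: np.ndarray, name: str = "points") -> np.ndarray:
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] not in (2, 3):
        raise ValueError(f"{name} must be a k x d matrix with d in (2, 3)")
    if arr.shape[0] < 2:
        raise DegenerateInputError(f"{name} needs at least 2 points")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def center(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Translate the column means to the origin; returns (centered, c)."""
    arr = _as_pointset(points)
    c = arr.mean(axis=0)
    return arr - c, c


def rmsd_scale(centered: np.ndarray) -> tuple[np.ndarray, float]:
    """Rescale a centered set so its root mean square distance from the
    origin is 1; returns (unit set, s) where s is the input's RMSD."""
    arr = np.asarray(centered, dtype=float)
    s = float(np.sqrt((arr**2).sum() / arr.shape[0]))
    if s == 0.0:
        raise DegenerateInputError("all points coincide; RMSD is zero")
    return arr / s, s


def optimal_rotation(
    X0: np.ndarray, Y0: np.ndarray, allow_reflection: bool = True
) -> np.ndarray:
    """Orthogonal T minimizing ||X0 - Y0 @ T|| for centered X0, Y0.

    Solved by the singular value decomposition of Y0' X0; with
    ``allow_reflection=False`` the minimizer is constrained to det(T) = +1
    by flipping the smallest singular direction when needed.
    """
    X0 = np.asarray(X0, dtype=float)
    Y0 = np.asarray(Y0, dtype=float)
    if X0.shape != Y0.shape:
        raise ValueError(f"shape mismatch: {X0.shape} vs {Y0.shape}")
    U, sigma, Vt = svd(Y0.T @ X0)
    if not allow_reflection and np.linalg.det(U @ Vt) < 0:
        U = U.copy()
        U[:, -1] *= -1.0
    return U @ Vt


def conform(
    X: np.ndarray, Y: np.ndarray, allow_reflection: bool = True
) -> AlignmentResult:
    """Optimally superimpose Y onto the reference X.

    Returns the jointly optimal (b, T, c), the conformed curve Z and the
    standardized dissimilarity D.  Both inputs must be non-degenerate
    equal-shape point sets.
    """
    X = _as_pointset(X, "X")
    Y = _as_pointset(Y, "Y")
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs Y {Y.shape}")

    Xc, mean_x = center(X)
    Yc, _ = center(Y)
    ssx = float((Xc**2).sum())
    ssy = float((Yc**2).sum())
    if ssx == 0.0:
        raise DegenerateInputError("reference X has zero spatial variance")
    if ssy == 0.0:
        raise DegenerateInputError("Y has zero spatial variance")

    U, sigma, Vt = svd(Yc.T @ Xc)
    if not allow_reflection and np.linalg.det(U @ Vt) < 0:
        U = U.copy()
        sigma = sigma.copy()
        U[:, -1] *= -1.0
        sigma[-1] *= -1.0
    T = U @ Vt
    trace = float(sigma.sum())

    b = trace / ssy
    Z = b * Yc @ T + mean_x
    resid = float(((Xc - b * Yc @ T) ** 2).sum())
    D = resid / ssx
    # guard the analytic [0, 1] range against round-off
    D = float(min(max(D, 0.0), 1.0))
    return AlignmentResult(b=b, T=T, c=mean_x, Z=Z, D=D)


def dissimilarity(
    X: np.ndarray, Y: np.ndarray, allow_reflection: bool = True
) -> float:
    """Standardized Procrustes dissimilarity D in [0, 1] of Y against X."""
    return conform(X, Y, allow_reflection=allow_reflection).D
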
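"""Convergence and accuracy metrics for Pareto front estimates.

The hypervolume indicator H_I compares the convex-hull volume enclosed
between the estimated front and a fixed reference point y_R (one
dominated by every front point) to the volume of the hypercuboid spanned
by the objective-space origin and y_R:

    H_I = 1 - H(F_hat, y_R) / H(0, y_R).

H_I = 0 means the front has collapsed onto the origin (a simultaneous
perfect fit on all objectives); H_I = 1 means the front carries no volume
at all.  The hull vertex set is the front points, y_R itself, and — for
each objective axis — y_R with that coordinate replaced by the front's
minimum on that objective; these axis projections close the hull so that
a perfect single-point front at the origin spans the full hypercuboid.

The complementary measure d_F_hat is the minimum Euclidean distance from
the front to the origin.  Across repeated optimisation runs both metrics
are summarised by their mean, sample SD and coefficient of variation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .fitness import PENALTY_VALUE

__all__ = [
    "reference_point",
    "hypervolume_indicator",
    "min_front_distance",
    "aggregate_runs",
]


def _finite_front(front) -> np.ndarray:
    F = np.asarray(front, dtype=float)
    if F.ndim == 1:
        F = F[None, :]
    # penalty individuals are excluded from all metrics
    return F[np.all(F < PENALTY_VALUE, axis=1)]


def reference_point(fronts: Iterable, margin: float = 0.0) -> np.ndarray:
    """Component-wise maximum over all finite front points, inflated by
    `margin` (fractional); dominated by every point it will be used with."""
    stacked = [_finite_front(f) for f in fronts]
    stacked = [f for f in stacked if len(f)]
    if not stacked:
        raise ValueError("no finite objective vectors to build a reference point from")
    y_r = np.vstack(stacked).max(axis=0)
    return y_r * (1.0 + margin)


def hypervolume_indicator(front, y_r: np.ndarray) -> float:
    """H_I = 1 - H(front, y_R) / H(0, y_R), via the convex hull of the
    front augmented with y_R and its per-axis projections through the
    front minima."""
    y_r = np.asarray(y_r, dtype=float)
    if np.any(y_r <= 0):
        raise ValueError("reference point must have strictly positive coordinates")
    F = _finite_front(front)
    if len(F) == 0:
        raise ValueError("front holds no finite objective vectors")
    if F.shape[1] != len(y_r):
        raise ValueError("front and reference point dimensions differ")
    if np.any(F > y_r + 1e-12 * np.abs(y_r)):
        raise ValueError("every front point must be dominated by the reference point")
    # vertex set: every corner obtained by replacing a subset of y_R's
    # coordinates with a front point's coordinates.  In 2-D this spans the
    # same hull as the front plus y_R plus its per-axis projections through
    # the front minima; in higher dimensions it is the set needed for a
    # perfect single-point front at the origin to span the full hypercuboid
    # (H_I = 0).
    d = len(y_r)
    corners = []
    for mask in range(2**d):
        pick = np.array([(mask >> i) & 1 for i in range(d)], dtype=bool)
        corners.append(np.where(pick, F, y_r[None, :]))
    vertices = np.unique(np.vstack(corners), axis=0)
    try:
        vol = ConvexHull(vertices).volume
    except QhullError:
        vol = 0.0  # degenerate (affinely dependent) vertex set
    box = float(np.prod(y_r))
    return float(1.0 - vol / box)


def min_front_distance(front) -> float:
    """Minimum Euclidean distance between the front and the objective-space
    origin; close to 0 indicates a good fit."""
    F = _finite_front(front)
    if len(F) == 0:
        raise ValueError("front holds no finite objective vectors")
    return float(np.min(np.linalg.norm(F, axis=1)))


def aggregate_runs(values: Sequence[float]) -> Tuple[float, float, float]:
    """(mean, sample SD, CV) of a per-run metric over independent runs.

    SD uses the n-1 denominator and is 0 for a single value; CV is
    SD/|mean|, 0 by convention when the mean is 0.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    cv = sd / abs(mean) if mean != 0 else 0.0
    return mean, sd, cv
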
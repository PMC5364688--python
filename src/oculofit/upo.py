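"""Unstable-periodic-orbit extraction from noisy nystagmus recordings.

Real nystagmus is nonperiodic: successive cycles differ slightly in
period, amplitude and shape.  To obtain a single representative cycle to
fit, the inter-cycle interval sequence {tau_k} (from velocity-threshold
crossings in the fast phase) is delay-embedded, w_k = (tau_k, ...,
tau_{k+d-1}), and the So transform

    G(w_n) = (I - DF(w_n))^{-1} (w_{n+1} - DF(w_n) w_n)

is applied, which concentrates the delay vectors onto the fixed points of
the interval return map F (exactly so for a linear map, since then
G(w) = (I - A)^{-1} b for every w).  Transformed points within a
cross-sectional tube around the delay-space diagonal are projected onto
the diagonal and histogram-binned; the tallest bin gives the orbit
period tau_*.  A cycle whose interval lies within tolerance of tau_* and
whose endpoints match most closely is then re-sectioned to start at a
fast-phase onset, oriented rightward and upsampled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional, Union

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .waveform import Cycle, differentiate

__all__ = [
    "IntervalSeries",
    "DelayEmbedding",
    "UPOCycle",
    "ExtractionError",
    "default_velocity_threshold",
    "detect_cycle_intervals",
    "delay_embed",
    "so_transform",
    "find_period_peak",
    "extract_upo_cycle",
    "extract_upo",
]

logger = logging.getLogger(__name__)


class ExtractionError(RuntimeError):
    """Raised when the UPO pipeline cannot extract a cycle."""


@dataclass(frozen=True)
class IntervalSeries:
    """Threshold-crossing times and the inter-cycle intervals between them."""

    crossing_times: np.ndarray
    intervals: np.ndarray

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.crossing_times) - 1:
            raise ValueError("need exactly one interval per successive crossing pair")
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be positive")


@dataclass(frozen=True)
class DelayEmbedding:
    """Sliding-window delay vectors of the interval sequence."""

    vectors: np.ndarray  # (N - d + 1, d)
    dimension: int

    def __post_init__(self) -> None:
        if self.dimension < 2:
            raise ValueError("embedding dimension must be >= 2")
        if self.vectors.shape[1] != self.dimension:
            raise ValueError("vector width must equal the embedding dimension")


@dataclass(frozen=True)
class UPOCycle:
    """A representative cycle plus its provenance."""

    cycle: Cycle
    tau_star: float
    source_id: str = ""


def _smoothed_velocity(gaze: np.ndarray, fs: float, window: float) -> np.ndarray:
    """Velocity of the gaze trace with a short moving-average smooth.

    Differentiation amplifies measurement noise by a factor ~fs; a moving
    average much shorter than the fast phase suppresses the chatter
    without shifting the threshold crossings appreciably."""
    v = differentiate(gaze, 1.0 / fs)
    w = max(1, int(round(window * fs)))
    if w > 1:
        kernel = np.ones(w) / w
        v = np.convolve(v, kernel, mode="same")
    return v


def default_velocity_threshold(gaze: np.ndarray, fs: float, smooth_window: float = 0.02) -> float:
    """Signed velocity threshold at roughly the middle of the fast phase.

    The fast-phase direction is the sign of the velocity extremum; the
    threshold is half the median of the per-cycle fast-phase peak
    velocities (peaks of the signed velocity above 30% of its maximum).
    """
    v = _smoothed_velocity(gaze, fs, smooth_window)
    sign = 1.0 if v[np.argmax(np.abs(v))] > 0 else -1.0
    sv = sign * v
    peaks, _ = find_peaks(sv, height=0.3 * sv.max())
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(sv))])
    return float(sign * 0.5 * np.median(sv[peaks]))


def detect_cycle_intervals(
    gaze: np.ndarray,
    fs: float,
    vthresh: Optional[float] = None,
    min_separation: float = 0.1,
    smooth_window: float = 0.02,
) -> IntervalSeries:
    """Inter-cycle intervals from sub-sample velocity-threshold crossings.

    Crossings are located where the (lightly smoothed) velocity passes
    `vthresh` in the fast-phase direction (upward for positive thresholds,
    downward for negative), with linear interpolation between samples.
    Crossings closer than `min_separation` seconds to the previous one are
    treated as chatter from noise within a single fast phase and dropped.
    """
    if fs <= 0:
        raise ValueError("sampling rate must be positive")
    gaze = np.asarray(gaze, float)
    if vthresh is None:
        vthresh = default_velocity_threshold(gaze, fs, smooth_window)
    v = _smoothed_velocity(gaze, fs, smooth_window)
    s = 1.0 if vthresh >= 0 else -1.0
    sv, thr = s * v, s * vthresh
    below = sv[:-1] < thr
    above = sv[1:] >= thr
    idx = np.where(below & above)[0]
    if len(idx) < 2:
        raise ExtractionError("fewer than 2 threshold crossings found")
    frac = (thr - sv[idx]) / (sv[idx + 1] - sv[idx])
    times = (idx + frac) / fs
    kept = [times[0]]
    for t in times[1:]:
        if t - kept[-1] >= min_separation:
            kept.append(t)
    times = np.asarray(kept)
    if len(times) < 2:
        raise ExtractionError("fewer than 2 separated crossings found")
    return IntervalSeries(crossing_times=times, intervals=np.diff(times))


def delay_embed(iv: Union[IntervalSeries, np.ndarray], dimension: int = 2) -> DelayEmbedding:
    """Method of delays: w_k = (tau_k, ..., tau_{k+d-1})."""
    taus = iv.intervals if isinstance(iv, IntervalSeries) else np.asarray(iv, float)
    n = len(taus) - dimension + 1
    if n < 1:
        raise ValueError("interval sequence shorter than the embedding dimension")
    vectors = np.stack([taus[i : i + n] for i in range(dimension)], axis=1)
    return DelayEmbedding(vectors=vectors, dimension=dimension)


def _local_jacobians(W: np.ndarray, k_neighbours: int):
    """Per-point local linear fits w_{j+1} ~ A w_j + b over the k nearest
    delay vectors; returns (A_n, b_n) arrays."""
    n_pairs = len(W) - 1
    d = W.shape[1]
    k = min(k_neighbours, n_pairs)
    A_all = np.empty((n_pairs, d, d))
    b_all = np.empty((n_pairs, d))
    X, Y = W[:-1], W[1:]
    for nn in range(n_pairs):
        dist = np.linalg.norm(X - W[nn], axis=1)
        near = np.argsort(dist, kind="stable")[:k]
        Xd = np.hstack([X[near], np.ones((k, 1))])
        coef, *_ = np.linalg.lstsq(Xd, Y[near], rcond=None)
        A_all[nn] = coef[:d].T
        b_all[nn] = coef[d]
    return A_all, b_all


def so_transform(
    emb: DelayEmbedding,
    k_neighbours: int = 8,
    jacobian: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> np.ndarray:
    """Apply the So transform G to every delay vector with a successor.

    The local Jacobian DF(w_n) is estimated by a least-squares linear fit
    of the one-step map over the `k_neighbours` nearest delay vectors,
    unless an exact `jacobian(w)` is supplied.  Points where I - DF is
    singular to working precision are skipped (with a logged count); if
    all points are skipped an ExtractionError is raised.
    """
    W = emb.vectors
    if len(W) < emb.dimension + 2:
        raise ValueError("need at least d + 2 delay vectors to estimate Jacobians")
    d = emb.dimension
    eye = np.eye(d)
    if jacobian is None:
        A_all, _ = _local_jacobians(W, k_neighbours)
    out = []
    skipped = 0
    for nn in range(len(W) - 1):
        A = np.asarray(jacobian(W[nn]), float) if jacobian is not None else A_all[nn]
        M = eye - A
        if np.linalg.cond(M) > 1e12:
            skipped += 1
            continue
        out.append(np.linalg.solve(M, W[nn + 1] - A @ W[nn]))
    if skipped:
        logger.info("so_transform skipped %d points with singular I - DF", skipped)
    if not out:
        raise ExtractionError("every point had a singular I - DF")
    return np.asarray(out)


def find_period_peak(
    points: np.ndarray,
    tube_diameter: float = 0.5,
    bin_width: float = 0.025,
) -> float:
    """Histogram peak of the diagonal projections of the transformed points.

    Points farther than tube_diameter/2 (perpendicular Euclidean distance)
    from the delay-space diagonal are discarded; survivors are projected
    orthogonally onto the diagonal, parameterised by the common coordinate
    tau (seconds), and binned with edges anchored at 0.  Returns the centre
    of the tallest bin, ties broken toward the smaller period.
    """
    P = np.asarray(points, float)
    if P.ndim == 1:
        P = P[None, :]
    if len(P) == 0:
        raise ExtractionError("no transformed points")
    proj = P.mean(axis=1)  # diagonal projection: the point (tau, ..., tau)
    perp = np.linalg.norm(P - proj[:, None], axis=1)
    inside = perp <= tube_diameter / 2.0
    if not np.any(inside):
        raise ExtractionError("no points inside the diagonal tube")
    taus = proj[inside]
    bins = np.floor(taus / bin_width).astype(int)
    uniq, counts = np.unique(bins, return_counts=True)
    best = uniq[counts == counts.max()].min()  # tie -> smaller period
    return float((best + 0.5) * bin_width)


def extract_upo_cycle(
    gaze: np.ndarray,
    fs: float,
    iv: IntervalSeries,
    tau_star: float,
    tol: float = 0.0125,
    upsample_factor: int = 10,
    source_id: str = "",
) -> UPOCycle:
    """Build the representative cycle for the orbit period `tau_star`.

    Among cycles whose interval is within `tol` of tau_star, the one with
    the smallest first-to-last gaze difference is chosen; three copies are
    concatenated and the section between two successive fast-phase onsets
    (velocity-threshold crossings of the tripled waveform) is taken, so
    the cycle starts at a fast phase.  The result is oriented with the
    fast phase rightward and spline-upsampled by `upsample_factor`
    (250 Hz -> 2500 Hz by default).
    """
    gaze = np.asarray(gaze, float)
    cand = np.where(np.abs(iv.intervals - tau_star) <= tol)[0]
    if len(cand) == 0:
        raise ExtractionError("no interval within tolerance of the histogram peak")
    best_k, best_gap, best_seg = -1, np.inf, None
    for k in cand:
        i0 = int(round(iv.crossing_times[k] * fs))
        i1 = int(round(iv.crossing_times[k + 1] * fs))
        seg = gaze[i0:i1]
        if len(seg) < 3:
            continue
        gap = abs(seg[0] - seg[-1])
        if gap < best_gap:
            best_k, best_gap, best_seg = k, gap, seg
    if best_seg is None:
        raise ExtractionError("all candidate cycles were degenerate")
    tripled = np.concatenate([best_seg, best_seg, best_seg])
    trip_iv = detect_cycle_intervals(tripled, fs, min_separation=0.25 * tau_star)
    times = trip_iv.crossing_times
    n_seg = len(best_seg)
    # pick the crossing pair inside the middle copy
    mid = times[(times >= n_seg / fs) & (times < 2 * n_seg / fs)]
    t_start = mid[0] if len(mid) else times[0]
    j0 = min(int(round(t_start * fs)), 2 * n_seg - 1)
    cycle_vals = tripled[j0 : j0 + n_seg + 1]  # inclusive endpoint: spans one period
    v = differentiate(cycle_vals, 1.0 / fs)
    if v[np.argmax(np.abs(v))] < 0:  # orient the fast phase rightward
        cycle_vals = -cycle_vals
    t_coarse = np.arange(n_seg + 1) / fs
    n_fine = n_seg * upsample_factor + 1
    t_fine = np.arange(n_fine) / (fs * upsample_factor)
    spline = CubicSpline(t_coarse, cycle_vals)
    # period on the sample grid; within one coarse sample of the interval
    period = n_seg / fs
    cycle = Cycle(
        times=t_fine,
        values=spline(t_fine),
        period=period,
        sample_interval=1.0 / (fs * upsample_factor),
    )
    return UPOCycle(cycle=cycle, tau_star=float(tau_star), source_id=source_id)


def extract_upo(
    gaze: np.ndarray,
    fs: float,
    vthresh: Optional[float] = None,
    dimension: int = 2,
    tube_diameter: float = 0.5,
    bin_width: float = 0.025,
    tol: float = 0.0125,
    k_neighbours: int = 8,
    upsample_factor: int = 10,
    source_id: str = "",
) -> UPOCycle:
    """Full pipeline: intervals -> delay embedding -> So transform ->
    histogram peak -> representative cycle."""
    iv = detect_cycle_intervals(gaze, fs, vthresh)
    emb = delay_embed(iv, dimension)
    pts = so_transform(emb, k_neighbours)
    tau_star = find_period_peak(pts, tube_diameter, bin_width)
    return extract_upo_cycle(
        gaze, fs, iv, tau_star, tol=tol, upsample_factor=upsample_factor, source_id=source_id
    )
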
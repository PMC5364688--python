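"""Cycle extraction and waveform utilities for simulated nystagmus traces.

A single oscillation period is cut from the post-transient part of a
simulated gaze trace: the first 2.4 s are discarded as transient dynamics,
the remainder is min-max normalised to [0, 1] *for boundary detection
only*, and local minima with normalised value below 0.2 mark cycle
boundaries (the 0.2 test filters shallow ripple minima that do not
terminate a cycle).  The returned cycle is the un-normalised gaze segment
between the last two boundary minima, so its amplitude information is
preserved for the shape objective.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline

from .integrate import Trajectory

__all__ = [
    "Cycle",
    "ExtractionResult",
    "extract_simulated_cycle",
    "rescale_and_resample",
    "differentiate",
    "local_minima",
]

OSCILLATORY = "oscillatory"
NON_OSCILLATORY = "non_oscillatory"


@dataclass(frozen=True)
class Cycle:
    """One period of a nystagmus waveform (gaze in degrees)."""

    times: np.ndarray      # seconds from 0, uniform
    values: np.ndarray     # gaze, deg
    period: float          # seconds
    sample_interval: float # seconds

    def __post_init__(self) -> None:
        t, x = np.asarray(self.times, float), np.asarray(self.values, float)
        if len(t) != len(x) or len(t) < 3:
            raise ValueError("cycle needs >= 3 aligned samples")
        if self.period <= 0:
            raise ValueError("period must be positive")
        if abs(t[0]) > 1e-12:
            raise ValueError("cycle times must start at 0")
        if abs(t[-1] - self.period) > self.sample_interval + 1e-12:
            raise ValueError("cycle must span its period to within one sample")

    @property
    def peak_to_peak(self) -> float:
        return float(np.ptp(self.values))


@dataclass(frozen=True)
class ExtractionResult:
    status: str
    cycle: Optional[Cycle] = None

    def __post_init__(self) -> None:
        if (self.status == OSCILLATORY) != (self.cycle is not None):
            raise ValueError("cycle must be present iff status is oscillatory")

    @property
    def oscillatory(self) -> bool:
        return self.status == OSCILLATORY


def local_minima(x: np.ndarray) -> np.ndarray:
    """Indices of strict three-point local minima; a flat run that is lower
    than both neighbours counts once, at its first index."""
    x = np.asarray(x, float)
    idx = []
    i = 1
    n = len(x)
    while i < n - 1:
        if x[i] < x[i - 1]:
            j = i
            while j + 1 < n and x[j + 1] == x[i]:
                j += 1
            if j + 1 < n and x[j + 1] > x[i]:
                idx.append(i)
            i = j + 1
        else:
            i += 1
    return np.asarray(idx, dtype=int)


def extract_simulated_cycle(
    traj: Trajectory,
    transient: float = 2.4,
    boundary_level: float = 0.2,
    amplitude_floor: float = 1e-6,
) -> ExtractionResult:
    """Cut one oscillation period from a simulated trajectory's gaze trace.

    Returns a non-oscillatory verdict when the post-transient peak-to-peak
    amplitude is below ``amplitude_floor`` (deg) or when fewer than two
    boundary minima (normalised value < ``boundary_level``) are found.
    """
    t, x = traj.times, traj.gaze
    if t[-1] <= transient:
        raise ValueError(f"trajectory must extend beyond the {transient} s transient window")
    keep = t >= transient
    t, x = t[keep], x[keep]
    span = np.ptp(x)
    if span < amplitude_floor:
        return ExtractionResult(NON_OSCILLATORY)
    norm = (x - x.min()) / span
    mins = local_minima(norm)
    bounds = mins[norm[mins] < boundary_level]
    if len(bounds) < 2:
        return ExtractionResult(NON_OSCILLATORY)
    i0, i1 = bounds[-2], bounds[-1]
    seg_t = t[i0 : i1 + 1] - t[i0]
    seg_x = x[i0 : i1 + 1]
    dt = float(t[1] - t[0])
    return ExtractionResult(
        OSCILLATORY,
        Cycle(times=seg_t, values=seg_x, period=float(seg_t[-1]), sample_interval=dt),
    )


def rescale_and_resample(c: Cycle, target: Cycle) -> np.ndarray:
    """Scale `c` in time to the target's period and cubic-interpolate its
    values onto the target's time mesh.  Output length equals the target's.
    """
    if c.period <= 0 or target.period <= 0:
        raise ValueError("periods must be positive")
    scaled_t = c.times * (target.period / c.period)
    spline = CubicSpline(scaled_t, c.values, extrapolate=True)
    return spline(target.times)


def differentiate(values: np.ndarray, dt: float) -> np.ndarray:
    """Velocity by central differences (one-sided at the ends)."""
    x = np.asarray(values, float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples to differentiate")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return np.gradient(x, dt)
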
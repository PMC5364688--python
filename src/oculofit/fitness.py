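"""Multi-objective fitness functions.

Nystagmus candidates are scored by two objectives: the RMS shape
difference d_S between the target cycle and the simulated cycle scaled to
the target period (compared in degrees, so amplitude information is
retained), and the absolute period difference d_P between the *unscaled*
periods.  An explicit amplitude objective is deliberately omitted: the
shape comparison alone is sufficient to drive solutions to the correct
amplitude.  Saccade candidates are scored by one RMS velocity-profile
difference per target amplitude (three objectives by default).

Candidates whose simulation is non-oscillatory (for nystagmus) or whose
integration fails are assigned the penalty value 1e60 on every objective,
which every finite objective vector dominates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .integrate import IntegrationError, SolverConfig, integrate, integrate_reference
from .model import ModelParameters, initial_state
from .waveform import Cycle, extract_simulated_cycle, rescale_and_resample

__all__ = [
    "PENALTY_VALUE",
    "ObjectiveVector",
    "SaccadeProfile",
    "SaccadeTargetSet",
    "shape_difference",
    "period_difference",
    "nystagmus_objectives",
    "saccade_objectives",
]

PENALTY_VALUE = 1e60

#: Solver settings used when evaluating candidates inside the GA.  The
#: resulting objective uncertainty (~1e-4 deg) is far below the scale on
#: which solutions are discriminated.
FITNESS_SOLVER = SolverConfig(rtol=1e-5, atol=1e-8)


@dataclass(frozen=True)
class ObjectiveVector:
    """Ordered non-negative fitness components, possibly penalty-valued."""

    components: Tuple[float, ...]
    penalty: bool = False

    def __post_init__(self) -> None:
        comps = tuple(float(c) for c in self.components)
        object.__setattr__(self, "components", comps)
        if self.penalty:
            if any(c != PENALTY_VALUE for c in comps):
                raise ValueError("penalty vectors must carry the penalty value on every component")
        else:
            if not all(np.isfinite(c) and c >= 0 for c in comps):
                raise ValueError("objective components must be finite and non-negative")

    @classmethod
    def of(cls, *components: float) -> "ObjectiveVector":
        return cls(tuple(components))

    @classmethod
    def penalised(cls, n_objectives: int) -> "ObjectiveVector":
        return cls(tuple([PENALTY_VALUE] * n_objectives), penalty=True)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.components, dtype=float)

    def __len__(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class SaccadeProfile:
    """A velocity profile (deg/s) on a uniform time mesh for one amplitude."""

    amplitude: float
    times: np.ndarray
    velocities: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        if len(t) != len(self.velocities) or len(t) < 2:
            raise ValueError("profile needs >= 2 aligned samples")
        dt = np.diff(t)
        if np.any(np.abs(dt - dt[0]) > 1e-9 * max(1.0, dt[0])):
            raise ValueError("profile mesh must be uniform")

    @property
    def peak_velocity(self) -> float:
        return float(np.max(self.velocities))


@dataclass(frozen=True)
class SaccadeTargetSet:
    """Velocity-profile targets for a set of strictly increasing amplitudes
    (5, 10 and 20 deg by default)."""

    profiles: Tuple[SaccadeProfile, ...]

    def __post_init__(self) -> None:
        amps = [pr.amplitude for pr in self.profiles]
        if len(amps) == 0 or any(a2 <= a1 for a1, a2 in zip(amps, amps[1:])):
            raise ValueError("amplitudes must be non-empty and strictly increasing")

    @property
    def amplitudes(self) -> Tuple[float, ...]:
        return tuple(pr.amplitude for pr in self.profiles)

    def __len__(self) -> int:
        return len(self.profiles)


def shape_difference(scaled: np.ndarray, target: np.ndarray) -> float:
    """RMS difference d_S = sqrt((1/N) sum (S_i - T_i)^2)."""
    s, t = np.asarray(scaled, float), np.asarray(target, float)
    if s.shape != t.shape or s.ndim != 1 or len(s) < 2:
        raise ValueError("series must be 1-D, equal-length, with N >= 2")
    return float(np.sqrt(np.mean((s - t) ** 2)))


def period_difference(tau_e: float, tau_t: float) -> float:
    """Absolute period difference d_P = |tau_E - tau_T| on unscaled periods."""
    if tau_e <= 0 or tau_t <= 0:
        raise ValueError("periods must be positive")
    return float(abs(tau_e - tau_t))


def nystagmus_objectives(
    p: ModelParameters,
    target: Cycle,
    cfg: SolverConfig = FITNESS_SOLVER,
    delta_g: float = 1.5,
) -> ObjectiveVector:
    """Bi-objective (d_S, d_P) score of a candidate against a target cycle.

    Integrates from rest with a 1.5-deg displacement command for
    ``cfg.t_end`` seconds, extracts one simulated cycle, scales it to the
    target period and compares in degrees.  Non-oscillatory candidates and
    failed integrations receive the penalty vector.
    """
    try:
        traj = integrate(p, initial_state(delta_g), cfg)
    except IntegrationError:
        return ObjectiveVector.penalised(2)
    res = extract_simulated_cycle(traj)
    if not res.oscillatory:
        return ObjectiveVector.penalised(2)
    scaled = rescale_and_resample(res.cycle, target)
    d_s = shape_difference(scaled, target.values)
    d_p = period_difference(res.cycle.period, target.period)
    return ObjectiveVector.of(d_s, d_p)


def saccade_objectives(
    p: ModelParameters,
    targets: SaccadeTargetSet,
    cfg: SolverConfig = FITNESS_SOLVER,
) -> ObjectiveVector:
    """Tri-objective (d_1, ..., d_J) score against saccade velocity targets.

    For each target amplitude the model is integrated from rest with that
    displacement command, its velocity is evaluated directly on the
    target's time mesh from onset (t=0) to the target's end point, and the
    RMS difference is taken — truncation to the target's end enforces
    equal lengths.
    """
    comps = []
    for prof in targets.profiles:
        try:
            traj = integrate_reference(
                p, initial_state(prof.amplitude), cfg, t_eval=prof.times
            )
        except IntegrationError:
            return ObjectiveVector.penalised(len(targets))
        comps.append(shape_difference(traj.velocity, prof.velocities))
    return ObjectiveVector.of(*comps)
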
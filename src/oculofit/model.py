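"""Six-ODE burst-neuron model of the horizontal saccadic system.

The model couples a second-order overdamped oculomotor plant (gaze ``g``,
eye velocity ``v``) to a leaky neural integrator ``n``, two mutually
inhibiting excitatory burst neuron (EBN) populations ``r`` (right) and
``l`` (left), and a resettable motor-error integrator ``m``:

    dg/dt = v
    dv/dt = -(1/T1 + 1/T2) v - g/(T1 T2) + n/(T1 T2) + (1/T1 + 1/T2)(r - l)
    dn/dt = -n/TN + (r - l)
    dr/dt = (1/eps) (-r - gamma r l^2 + F(m))
    dl/dt = (1/eps) (-l - gamma l r^2 + F(-m))
    dm/dt = -(r - l)

The EBN firing rate is a saturating nonlinearity of the motor error,

    F(m) = alpha_on (1 - exp(-m / beta_on))   for m >= 0 (on-response)
    F(m) = -(alpha / beta) m exp(m / beta)    for m < 0  (off/braking response)

Six parameters {alpha, beta, eps, gamma, alpha_on, beta_on} are free; the
plant time constants T1, T2 and the integrator time constant TN are fixed
physiological constants.

Note on the damping term: some printed statements of the model carry
``-(1/T1 - 1/T2) v``, which makes the plant an unstable second-order
system for T1 > T2.  The overdamped form ``-(1/T1 + 1/T2) v`` (plant
eigenvalues -1/T1 and -1/T2) is used here by default; the alternative
sign is available through the ``printed_damping`` flag for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterator, Mapping, Tuple

import numpy as np

__all__ = [
    "STATE_VARS",
    "FREE_PARAMS",
    "ModelParameters",
    "ModelState",
    "Bounds",
    "DEFAULT_BOUNDS",
    "burst_response",
    "vector_field",
    "initial_state",
]

#: State component order used throughout the package.
STATE_VARS: Tuple[str, ...] = ("g", "v", "n", "r", "l", "m")

#: The six free parameters searched by the genetic algorithm, in the
#: canonical decision-vector order.
FREE_PARAMS: Tuple[str, ...] = ("alpha", "beta", "epsilon", "gamma", "alpha_on", "beta_on")


@dataclass(frozen=True)
class ModelParameters:
    """Free parameters of the burst-neuron model plus fixed plant constants.

    Parameters
    ----------
    alpha : float
        Off-response (braking) magnitude.
    beta : float
        Off-response range (deg).
    epsilon : float
        Burst-neuron response time (s); smaller values give faster EBN
        responses and a stiffer system.
    gamma : float
        Strength of the mutual inhibition between the two EBN populations.
    alpha_on : float
        On-response saturation magnitude (alpha prime).
    beta_on : float
        On-response range (beta prime, deg).
    T1, T2 : float
        Oculomotor plant time constants, 0.15 s and 0.012 s.
    TN : float
        Leaky neural-integrator time constant, 25 s.
    """

    alpha: float
    beta: float
    epsilon: float
    gamma: float
    alpha_on: float
    beta_on: float
    T1: float = 0.15
    T2: float = 0.012
    TN: float = 25.0

    def __post_init__(self) -> None:
        if not (self.T1 > 0 and self.T2 > 0 and self.TN > 0):
            raise ValueError("plant time constants must be strictly positive")
        for name in FREE_PARAMS:
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite parameter {name!r}")

    def free_array(self) -> np.ndarray:
        """The six free parameters as an array in `FREE_PARAMS` order."""
        return np.array([getattr(self, k) for k in FREE_PARAMS], dtype=float)

    @classmethod
    def from_free_array(cls, x, **fixed) -> "ModelParameters":
        x = np.asarray(x, dtype=float)
        if x.shape != (len(FREE_PARAMS),):
            raise ValueError(f"expected {len(FREE_PARAMS)} free parameters, got shape {x.shape}")
        return cls(**dict(zip(FREE_PARAMS, x)), **fixed)

    def to_dict(self) -> Dict[str, float]:
        """Flat key-value form used for YAML/JSON config blocks."""
        keys = FREE_PARAMS + ("T1", "T2", "TN")
        return {k: float(getattr(self, k)) for k in keys}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ModelParameters":
        known = set(FREE_PARAMS) | {"T1", "T2", "TN"}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def replace(self, **kw) -> "ModelParameters":
        return replace(self, **kw)


@dataclass(frozen=True)
class ModelState:
    """One point of the six-dimensional model state."""

    g: float = 0.0
    v: float = 0.0
    n: float = 0.0
    r: float = 0.0
    l: float = 0.0
    m: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("state components must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.g, self.v, self.n, self.r, self.l, self.m], dtype=float)

    @classmethod
    def from_array(cls, x) -> "ModelState":
        x = np.asarray(x, dtype=float)
        if x.shape != (6,):
            raise ValueError(f"state must have 6 components, got shape {x.shape}")
        return cls(*x)


@dataclass(frozen=True)
class Bounds:
    """Per-parameter (low, high) box for the six free parameters."""

    alpha: Tuple[float, float] = (1.0, 1000.0)
    beta: Tuple[float, float] = (0.1, 60.0)
    epsilon: Tuple[float, float] = (1e-5, 0.1)
    gamma: Tuple[float, float] = (0.0, 12.0)
    alpha_on: Tuple[float, float] = (50.0, 1000.0)
    beta_on: Tuple[float, float] = (0.1, 60.0)

    def __post_init__(self) -> None:
        for name in FREE_PARAMS:
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"bounds for {name!r} must satisfy low < high")

    def low(self) -> np.ndarray:
        return np.array([getattr(self, k)[0] for k in FREE_PARAMS], dtype=float)

    def high(self) -> np.ndarray:
        return np.array([getattr(self, k)[1] for k in FREE_PARAMS], dtype=float)

    def contains(self, p: "ModelParameters | np.ndarray", atol: float = 0.0) -> bool:
        x = p.free_array() if isinstance(p, ModelParameters) else np.asarray(p, dtype=float)
        return bool(np.all(x >= self.low() - atol) and np.all(x <= self.high() + atol))

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(x, dtype=float), self.low(), self.high())

    def with_gamma_high(self, hi: float) -> "Bounds":
        """The box with the gamma upper bound raised (used up to 150 for
        waveforms needing stronger mutual inhibition)."""
        return replace(self, gamma=(self.gamma[0], hi))

    def items(self) -> Iterator[Tuple[str, Tuple[float, float]]]:
        return ((k, getattr(self, k)) for k in FREE_PARAMS)

    def to_dict(self) -> Dict[str, Tuple[float, float]]:
        return {k: tuple(map(float, getattr(self, k))) for k in FREE_PARAMS}

    @classmethod
    def from_dict(cls, d: Mapping) -> "Bounds":
        return cls(**{k: tuple(map(float, v)) for k, v in d.items()})


#: The default search box for the genetic algorithm.
DEFAULT_BOUNDS = Bounds()


def validate_parameters(p: ModelParameters, bounds: Bounds = DEFAULT_BOUNDS) -> None:
    """Check `p` against `bounds`, raising ValueError on violation.

    Validation is an explicit, separate step: out-of-box exploratory
    parameter values remain constructible and integrable.
    """
    x = p.free_array()
    lo, hi = bounds.low(), bounds.high()
    bad = [FREE_PARAMS[i] for i in range(len(x)) if not (lo[i] <= x[i] <= hi[i])]
    if bad:
        raise ValueError(f"parameters out of bounds: {bad}")


def burst_response(m, p: ModelParameters):
    """EBN firing rate F(m) as a function of motor error (deg).

    Saturates to ``alpha_on`` for large positive errors (on-response) and
    forms a braking pulse of peak ``alpha / e`` at ``m = -beta`` for
    negative errors (off-response).  Continuous at m = 0 where both
    branches vanish.  Accepts scalars or arrays.
    """
    m_arr = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m_arr)):
        raise ValueError("motor error must be finite")
    pos = m_arr >= 0.0
    # evaluate each branch only on its own domain to avoid spurious overflow
    m_on = np.where(pos, m_arr, 0.0)
    m_off = np.where(pos, 0.0, m_arr)
    on = p.alpha_on * -np.expm1(-m_on / p.beta_on)
    off = -(p.alpha / p.beta) * m_off * np.exp(m_off / p.beta)
    out = np.where(pos, on, off)
    return float(out) if np.isscalar(m) else out


def vector_field(s: ModelState, p: ModelParameters, printed_damping: bool = False) -> np.ndarray:
    """Time derivative of the model state, in `STATE_VARS` order.

    With ``printed_damping=True`` the velocity damping coefficient is
    ``-(1/T1 - 1/T2)`` instead of the default overdamped ``-(1/T1 + 1/T2)``.
    """
    g, v, n, r, l, m = s.as_array()
    Fm = burst_response(m, p)
    Fmm = burst_response(-m, p)
    pulse = (1.0 / p.T1 + 1.0 / p.T2)
    damp = (1.0 / p.T1 - 1.0 / p.T2) if printed_damping else pulse
    q = 1.0 / (p.T1 * p.T2)
    return np.array(
        [
            v,
            -damp * v - q * g + q * n + pulse * (r - l),
            -n / p.TN + (r - l),
            (-r - p.gamma * r * l * l + Fm) / p.epsilon,
            (-l - p.gamma * l * r * r + Fmm) / p.epsilon,
            -(r - l),
        ]
    )


def initial_state(delta_g: float) -> ModelState:
    """Rest in the primary position with a pending displacement command.

    All state components are zero except the motor error, which is set to
    the target displacement ``delta_g`` (deg) — e.g. 1.5 for nystagmus
    fitting, or 5/10/20 for the standard saccade amplitudes.
    """
    if not np.isfinite(delta_g):
        raise ValueError("delta_g must be finite")
    return ModelState(m=float(delta_g))
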
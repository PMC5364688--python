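"""Numba-compiled right-hand side, Jacobian and implicit-midpoint stepper.

The kernels operate on a packed parameter vector
``pvec = (alpha, beta, epsilon, gamma, alpha_on, beta_on, T1, T2, TN, damp_sign)``
where ``damp_sign`` is +1 for the overdamped velocity damping
``-(1/T1 + 1/T2) v`` and -1 for the alternative ``-(1/T1 - 1/T2) v``.
State order matches :data:`oculofit.model.STATE_VARS`.
"""

from __future__ import annotations

import numpy as np
from numba import njit


def pack_params(p, printed_damping: bool = False) -> np.ndarray:
    """Pack a ModelParameters into the flat vector the kernels consume."""
    return np.array(
        [p.alpha, p.beta, p.epsilon, p.gamma, p.alpha_on, p.beta_on,
         p.T1, p.T2, p.TN, -1.0 if printed_damping else 1.0],
        dtype=float,
    )


@njit(cache=True)
def rhs(t, y, pvec):
    alpha, beta, eps, gamma, a_on, b_on, T1, T2, TN, dsign = (
        pvec[0], pvec[1], pvec[2], pvec[3], pvec[4], pvec[5],
        pvec[6], pvec[7], pvec[8], pvec[9],
    )
    g, v, n, r, l, m = y[0], y[1], y[2], y[3], y[4], y[5]
    if m >= 0.0:
        Fm = a_on * (1.0 - np.exp(-m / b_on))
        Fmm = (alpha / beta) * m * np.exp(-m / beta)   # F(-m), -m <= 0
    else:
        Fm = -(alpha / beta) * m * np.exp(m / beta)
        Fmm = a_on * (1.0 - np.exp(m / b_on))          # F(-m), -m > 0
    pulse = 1.0 / T1 + 1.0 / T2
    damp = 1.0 / T1 + dsign / T2
    q = 1.0 / (T1 * T2)
    out = np.empty(6)
    out[0] = v
    out[1] = -damp * v - q * g + q * n + pulse * (r - l)
    out[2] = -n / TN + (r - l)
    out[3] = (-r - gamma * r * l * l + Fm) / eps
    out[4] = (-l - gamma * l * r * r + Fmm) / eps
    out[5] = -(r - l)
    return out


@njit(cache=True)
def jac(t, y, pvec):
    alpha, beta, eps, gamma, a_on, b_on, T1, T2, TN, dsign = (
        pvec[0], pvec[1], pvec[2], pvec[3], pvec[4], pvec[5],
        pvec[6], pvec[7], pvec[8], pvec[9],
    )
    r, l, m = y[3], y[4], y[5]
    J = np.zeros((6, 6))
    pulse = 1.0 / T1 + 1.0 / T2
    damp = 1.0 / T1 + dsign / T2
    q = 1.0 / (T1 * T2)
    if m >= 0.0:
        dFm = (a_on / b_on) * np.exp(-m / b_on)
        # d/dm F(-m) with -m <= 0: (alpha/beta) e^{-m/beta} (1 - m/beta)
        dFmm = (alpha / beta) * np.exp(-m / beta) * (1.0 - m / beta)
    else:
        dFm = -(alpha / beta) * np.exp(m / beta) * (1.0 + m / beta)
        dFmm = -(a_on / b_on) * np.exp(m / b_on)
    J[0, 1] = 1.0
    J[1, 0] = -q
    J[1, 1] = -damp
    J[1, 2] = q
    J[1, 3] = pulse
    J[1, 4] = -pulse
    J[2, 2] = -1.0 / TN
    J[2, 3] = 1.0
    J[2, 4] = -1.0
    J[3, 3] = (-1.0 - gamma * l * l) / eps
    J[3, 4] = (-2.0 * gamma * r * l) / eps
    J[3, 5] = dFm / eps
    J[4, 3] = (-2.0 * gamma * l * r) / eps
    J[4, 4] = (-1.0 - gamma * r * r) / eps
    J[4, 5] = dFmm / eps
    J[5, 3] = -1.0
    J[5, 4] = 1.0
    return J


@njit(cache=True)
def midpoint_path(y0, t0, dt, n_steps, pvec, newton_tol, newton_maxit):
    """Fixed-step implicit midpoint integration of the model.

    Each step solves x = y + dt * f(t + dt/2, (y + x)/2) by a Newton
    iteration with the analytic Jacobian, converged when every residual
    component satisfies |res_i| <= newton_tol * max(1, |x_i|).

    Returns (path, fail_step): path has shape (n_steps + 1, 6); fail_step
    is -1 on success, else the 1-based index of the non-converged step.
    """
    path = np.empty((n_steps + 1, 6))
    path[0] = y0
    y = y0.copy()
    eye = np.eye(6)
    for k in range(n_steps):
        t_mid = t0 + k * dt + 0.5 * dt
        # explicit Euler predictor
        x = y + dt * rhs(t_mid, y, pvec)
        ok = False
        for _ in range(newton_maxit):
            mid = 0.5 * (y + x)
            res = x - y - dt * rhs(t_mid, mid, pvec)
            conv = True
            for i in range(6):
                if np.abs(res[i]) > newton_tol * max(1.0, np.abs(x[i])):
                    conv = False
                    break
            if conv:
                ok = True
                break
            A = eye - 0.5 * dt * jac(t_mid, mid, pvec)
            x = x - np.linalg.solve(A, res)
        if not ok:
            return path, k + 1
        y = x
        path[k + 1] = y
    return path, -1
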
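"""Numba-compiled right-hand sides and Jacobians for the ODE solvers.

These kernels are the hot path of the package: parameter sweeps and the
rank-volatility analysis integrate the model O(1e5) times, so the
derivative and Jacobian evaluations are compiled.  The public, validated
entry points live in :mod:`phageweapons.model`; the kernels assume clean
inputs and a scalar interaction coefficient.

State ordering: ``(F, B, N, P, Bt, Ft)`` for the interaction-based (gLV)
variant and ``(F, B, N, P, Bt, Ft, R)`` for the resource-explicit variant.
Parameter tuple ordering (both variants):
``(r, mu, kF, kN, lam, alpha, delta, beta, pi, pool_tildes)`` followed by
``(k, yield_per_cell)`` for the nutrient kernel, where ``mu`` is unused in
the nutrient variant and ``pool_tildes`` is 1.0/0.0.
"""

import numpy as np
from numba import njit

__all__ = ["glv_rhs", "glv_jac", "nutrient_rhs", "nutrient_jac"]


@njit(cache=True)
def glv_rhs(y, t, r, mu, kF, kN, lam, alpha, delta, beta, pi, pool_tildes):
    F, B, N, P, Bt, Ft = y
    S = F + B + N + pool_tildes * (Bt + Ft)
    g = r + mu * S
    aP = alpha * P
    out = np.empty(6)
    out[0] = F * (g - kF)
    out[1] = B * (g - aP)
    out[2] = B * aP * (1.0 - pi) + N * (g - kN)
    out[3] = beta * lam * (Bt + Ft) - aP * B - delta * P
    out[4] = kN * N + alpha * pi * B * P - lam * Bt
    out[5] = kF * F - lam * Ft
    return out


@njit(cache=True)
def glv_jac(y, t, r, mu, kF, kN, lam, alpha, delta, beta, pi, pool_tildes):
    F, B, N, P, Bt, Ft = y
    S = F + B + N + pool_tildes * (Bt + Ft)
    g = r + mu * S
    mt = mu * pool_tildes
    J = np.zeros((6, 6))
    # dF/dt = F*(g - kF)
    J[0, 0] = g - kF + F * mu
    J[0, 1] = F * mu
    J[0, 2] = F * mu
    J[0, 4] = F * mt
    J[0, 5] = F * mt
    # dB/dt = B*(g - alpha*P)
    J[1, 0] = B * mu
    J[1, 1] = g - alpha * P + B * mu
    J[1, 2] = B * mu
    J[1, 3] = -alpha * B
    J[1, 4] = B * mt
    J[1, 5] = B * mt
    # dN/dt = B*alpha*P*(1-pi) + N*(g - kN)
    J[2, 0] = N * mu
    J[2, 1] = alpha * P * (1.0 - pi) + N * mu
    J[2, 2] = g - kN + N * mu
    J[2, 3] = alpha * B * (1.0 - pi)
    J[2, 4] = N * mt
    J[2, 5] = N * mt
    # dP/dt
    J[3, 1] = -alpha * P
    J[3, 3] = -alpha * B - delta
    J[3, 4] = beta * lam
    J[3, 5] = beta * lam
    # dBt/dt
    J[4, 1] = alpha * pi * P
    J[4, 2] = kN
    J[4, 3] = alpha * pi * B
    J[4, 4] = -lam
    # dFt/dt
    J[5, 0] = kF
    J[5, 5] = -lam
    return J


@njit(cache=True)
def nutrient_rhs(y, t, r, mu, kF, kN, lam, alpha, delta, beta, pi,
                 pool_tildes, k, yield_per_cell):
    F, B, N, P, Bt, Ft, R = y
    g = R / (R + k)
    rg = r * g
    aP = alpha * P
    out = np.empty(7)
    out[0] = F * (rg - kF)
    out[1] = B * (rg - aP)
    out[2] = B * aP * (1.0 - pi) + N * (rg - kN)
    out[3] = beta * lam * (Bt + Ft) - aP * B - delta * P
    out[4] = kN * N + alpha * pi * B * P - lam * Bt
    out[5] = kF * F - lam * Ft
    out[6] = -yield_per_cell * rg * (F + B + N)
    return out


@njit(cache=True)
def nutrient_jac(y, t, r, mu, kF, kN, lam, alpha, delta, beta, pi,
                 pool_tildes, k, yield_per_cell):
    F, B, N, P, Bt, Ft, R = y
    g = R / (R + k)
    rg = r * g
    dg = k / ((R + k) * (R + k))  # dg/dR
    rdg = r * dg
    J = np.zeros((7, 7))
    J[0, 0] = rg - kF
    J[0, 6] = F * rdg
    J[1, 1] = rg - alpha * P
    J[1, 3] = -alpha * B
    J[1, 6] = B * rdg
    J[2, 1] = alpha * P * (1.0 - pi)
    J[2, 2] = rg - kN
    J[2, 3] = alpha * B * (1.0 - pi)
    J[2, 6] = N * rdg
    J[3, 1] = -alpha * P
    J[3, 3] = -alpha * B - delta
    J[3, 4] = beta * lam
    J[3, 5] = beta * lam
    J[4, 1] = alpha * pi * P
    J[4, 2] = kN
    J[4, 3] = alpha * pi * B
    J[4, 4] = -lam
    J[5, 0] = kF
    J[5, 5] = -lam
    J[6, 0] = -yield_per_cell * rg
    J[6, 1] = -yield_per_cell * rg
    J[6, 2] = -yield_per_cell * rg
    J[6, 6] = -yield_per_cell * rdg * (F + B + N)
    return J
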
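"""Numba-jitted kernels for the cell-quota ODE system.

The public API lives in :mod:`iasmark.model`; this module holds the raw
right-hand side and a fixed-step piecewise RK4 integrator used where many
thousands of short simulations are needed (segment calibration, virtual
patient generation).  Parameter vectors use the layout defined by
``PARAM_ORDER``.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

# Layout of the packed parameter vector consumed by the jitted kernels.
PARAM_ORDER = (
    "mu", "q1", "q2", "d", "c", "K",
    "gamma1", "gamma2", "A0", "delta", "m",
    "b", "sigma1", "sigma2", "eps",
)
N_PARAMS = len(PARAM_ORDER) + 1  # + psa-law flag

Q_FLOOR = 1e-9


@njit(cache=True)
def rhs_packed(x1, x2, Q, A, P, u, p):
    """Derivatives (dx1, dx2, dQ, dA, dP) of the two-subclone quota model.

    ``u`` is the treatment indicator: 0 during androgen suppression,
    1 off treatment.  ``p[15]`` selects the PSA production law
    (0 = proliferation-gated, 1 = linear in tumor volume).
    """
    mu = p[0]; q1 = p[1]; q2 = p[2]; d = p[3]; c = p[4]; K = p[5]
    g1 = p[6]; g2 = p[7]; A0 = p[8]; dl = p[9]; m = p[10]
    b = p[11]; s1 = p[12]; s2 = p[13]; eps = p[14]; linear = p[15]

    if Q < Q_FLOOR:
        Q = Q_FLOOR
    tot = x1 + x2
    gate1 = 1.0 - q1 / Q
    gate2 = 1.0 - q2 / Q

    pro1 = mu * gate1 * x1
    if pro1 < 0.0:
        pro1 = 0.0
    pro2 = mu * gate2 * x2
    if pro2 < 0.0:
        pro2 = 0.0
    trans = c * K / (Q + K) * x1

    dx1 = pro1 - d * x1 * tot - trans
    dx2 = pro2 - d * x2 * tot + trans
    dA = g1 * u * (1.0 - A / A0) + g2 - dl * A

    if tot > 0.0:
        cons = (mu * (Q - q1) * x1 + mu * (Q - q2) * x2) / tot
    else:
        cons = 0.0
    dQ = m * (A - Q) - cons

    if linear > 0.5:
        prod = s1 * x1 + s2 * x2
    else:
        p1 = s1 * gate1 * x1
        if p1 < 0.0:
            p1 = 0.0
        p2 = s2 * gate2 * x2
        if p2 < 0.0:
            p2 = 0.0
        prod = p1 + p2
    dP = b * Q + prod - eps * P

    return dx1, dx2, dQ, dA, dP


@njit(cache=True)
def _rk4_span(y, t0, t1, u, p, dt):
    """Advance state ``y`` in place from t0 to t1 at constant u."""
    span = t1 - t0
    if span <= 0.0:
        return
    n = int(span / dt) + 1
    h = span / n
    for _ in range(n):
        x1 = y[0]; x2 = y[1]; Q = y[2]; A = y[3]; P = y[4]
        k1 = rhs_packed(x1, x2, Q, A, P, u, p)
        k2 = rhs_packed(x1 + 0.5 * h * k1[0], x2 + 0.5 * h * k1[1],
                        Q + 0.5 * h * k1[2], A + 0.5 * h * k1[3],
                        P + 0.5 * h * k1[4], u, p)
        k3 = rhs_packed(x1 + 0.5 * h * k2[0], x2 + 0.5 * h * k2[1],
                        Q + 0.5 * h * k2[2], A + 0.5 * h * k2[3],
                        P + 0.5 * h * k2[4], u, p)
        k4 = rhs_packed(x1 + h * k3[0], x2 + h * k3[1], Q + h * k3[2],
                        A + h * k3[3], P + h * k3[4], u, p)
        for j in range(5):
            y[j] = y[j] + h / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
            if y[j] < 0.0:
                y[j] = 0.0
        if y[2] < Q_FLOOR:
            y[2] = Q_FLOOR


@njit(cache=True)
def integrate_piecewise(y0, t0, t_out, switch_times, u_values, p, dt):
    """Fixed-step RK4 through a piecewise-constant treatment schedule.

    ``switch_times``/``u_values``: u(t) = u_values[i] on
    [switch_times[i], switch_times[i+1]); the last u extends to +inf.
    Returns states at ``t_out`` (ascending, >= t0).
    """
    out = np.empty((t_out.shape[0], 5))
    y = y0.copy()
    t = t0
    # index of the piece containing t
    k = 0
    while k + 1 < switch_times.shape[0] and switch_times[k + 1] <= t:
        k += 1
    for i in range(t_out.shape[0]):
        target = t_out[i]
        while k + 1 < switch_times.shape[0] and switch_times[k + 1] < target:
            _rk4_span(y, t, switch_times[k + 1], u_values[k], p, dt)
            t = switch_times[k + 1]
            k += 1
        _rk4_span(y, t, target, u_values[k], p, dt)
        t = target
        for j in range(5):
            out[i, j] = y[j]
    return out
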
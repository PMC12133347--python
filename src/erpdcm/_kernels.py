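"""JIT-compiled numerical kernels for the ERP neural mass model.

Two hot paths live here:

* plain forward Euler integration of the 9-state ODE system, and
* Euler integration with simultaneous forward-sensitivity propagation,
  producing the downsampled pyramidal voltage together with its exact
  derivative with respect to all ten parameters.

The sensitivity recursion is the discrete (differentiate-then-discretize is
identical to discretize-then-differentiate for forward Euler) tangent of the
integration loop:

    S_{k+1} = S_k + dt * (J_x(x_k) S_k + J_theta(x_k)),   S_0 = 0,

with ``S = d x / d theta`` a 9x10 matrix, so gradient-based inference sees
derivatives that are exact for the simulator actually used, not a smooth
idealization of it.

Parameter ordering everywhere: (g1, g2, g3, g4, delta, tau_i, h_i, tau_e,
h_e, u) — see :data:`erpdcm.params.PARAM_NAMES`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["euler_path", "euler_observe", "euler_observe_sens"]


@njit(cache=True, inline="always", fastmath={"contract", "reassoc", "nsz", "arcp"})
def _sig(v):
    # 1/(1+exp(-0.56 v)) - 0.5, written to avoid overflow for large |v|
    if v >= 0.0:
        e = np.exp(-0.56 * v)
        return 1.0 / (1.0 + e) - 0.5
    e = np.exp(0.56 * v)
    return e / (1.0 + e) - 0.5


@njit(cache=True, inline="always", fastmath={"contract", "reassoc", "nsz", "arcp"})
def _dsig(v):
    # derivative of _sig: 0.56 e / (1+e)^2 with e = exp(-0.56 |v|) (symmetric)
    e = np.exp(-0.56 * abs(v))
    r = 1.0 + e
    return 0.56 * e / (r * r)


@njit(cache=True, inline="always", fastmath={"contract", "reassoc", "nsz", "arcp"})
def _rhs_inplace(x, t, u_on, f):
    g1, g2, g3, g4 = t[0], t[1], t[2], t[3]
    d, ti, hi, te, he, u = t[4], t[5], t[6], t[7], t[8], t[9]
    uu = u if u_on else 0.0
    z1 = x[0] - d * x[3]
    z7 = x[6] - d * x[7]
    z9 = x[8] - d * (x[4] - x[5])
    s1 = _sig(z1)
    s7 = _sig(z7)
    s9 = _sig(z9)
    te2 = te * te
    ti2 = ti * ti
    f[0] = x[3]
    f[1] = x[4]
    f[2] = x[5]
    f[3] = (he / te) * (g1 * s9 + uu) - x[0] / te2 - 2.0 * x[3] / te
    f[4] = g2 * (he / te) * s1 - x[1] / te2 - 2.0 * x[4] / te
    f[5] = g4 * (hi / ti) * s7 - x[2] / ti2 - 2.0 * x[5] / ti
    f[6] = x[7]
    f[7] = g3 * (he / te) * s9 - x[6] / te2 - 2.0 * x[7] / te
    f[8] = x[4] - x[5]


@njit(cache=True, fastmath={"contract", "reassoc", "nsz", "arcp"})
def euler_path(theta, x0, dt, n_steps, u_on, blowup):
    """Forward Euler path of the 9-state system.

    Returns (states[(n_steps+1) x 9], stable, n_valid).  On blow-up the
    offending sample is recorded, the remainder of the array is NaN-filled
    and integration stops; ``n_valid`` is the number of recorded samples.
    """
    out = np.full((n_steps + 1, 9), np.nan)
    x = x0.copy()
    f = np.empty(9)
    out[0] = x
    for i in range(9):
        if not (abs(x[i]) <= blowup):
            return out, False, 1
    for k in range(n_steps):
        _rhs_inplace(x, theta, u_on, f)
        for i in range(9):
            x[i] = x[i] + dt * f[i]
        out[k + 1] = x
        for i in range(9):
            # NaN-safe under fastmath flags: comparison with NaN is False
            if not (abs(x[i]) <= blowup):
                return out, False, k + 2
    return out, True, n_steps + 1


@njit(cache=True, fastmath={"contract", "reassoc", "nsz", "arcp"})
def euler_observe(theta, dt, n_steps, ds, blowup):
    """Downsampled pyramidal voltage x9 from the origin with input on.

    Returns (y[(n_steps // ds) + 1], stable).  y is NaN past a blow-up.
    """
    n_obs = n_steps // ds + 1
    y = np.full(n_obs, np.nan)
    x = np.zeros(9)
    f = np.empty(9)
    y[0] = 0.0
    for k in range(n_steps):
        _rhs_inplace(x, theta, True, f)
        for i in range(9):
            x[i] = x[i] + dt * f[i]
        for i in range(9):
            # NaN-safe under fastmath flags: comparison with NaN is False
            if not (abs(x[i]) <= blowup):
                return y, False
        if (k + 1) % ds == 0:
            y[(k + 1) // ds] = x[8]
    return y, True


@njit(cache=True, fastmath={"contract", "reassoc", "nsz", "arcp"})
def euler_observe_sens(theta, dt, n_steps, ds, blowup):
    """Downsampled x9 and its sensitivity to all ten parameters.

    Returns (y[n_obs], sens[n_obs x 10], stable).  The sensitivity is the
    exact derivative of the discrete Euler map.
    """
    n_obs = n_steps // ds + 1
    y = np.full(n_obs, np.nan)
    sy = np.zeros((n_obs, 10))
    g1, g2, g3, g4 = theta[0], theta[1], theta[2], theta[3]
    d, ti, hi, te, he, u = theta[4], theta[5], theta[6], theta[7], theta[8], theta[9]
    te2 = te * te
    te3 = te2 * te
    ti2 = ti * ti
    ti3 = ti2 * ti
    he_te = he / te
    hi_ti = hi / ti

    x = np.zeros(9)
    S = np.zeros((9, 10))
    f = np.empty(9)
    dS = np.empty((9, 10))
    y[0] = 0.0
    for k in range(n_steps):
        z1 = x[0] - d * x[3]
        z7 = x[6] - d * x[7]
        z9 = x[8] - d * (x[4] - x[5])
        s1 = _sig(z1)
        s7 = _sig(z7)
        s9 = _sig(z9)
        a4 = he_te * g1 * _dsig(z9)
        b5 = g2 * he_te * _dsig(z1)
        c6 = g4 * hi_ti * _dsig(z7)
        d8 = g3 * he_te * _dsig(z9)
        x9dot = x[4] - x[5]

        f[0] = x[3]
        f[1] = x[4]
        f[2] = x[5]
        f[3] = he_te * (g1 * s9 + u) - x[0] / te2 - 2.0 * x[3] / te
        f[4] = g2 * he_te * s1 - x[1] / te2 - 2.0 * x[4] / te
        f[5] = g4 * hi_ti * s7 - x[2] / ti2 - 2.0 * x[5] / ti
        f[6] = x[7]
        f[7] = g3 * he_te * s9 - x[6] / te2 - 2.0 * x[7] / te
        f[8] = x9dot

        for j in range(10):
            dz9 = S[8, j] - d * (S[4, j] - S[5, j])
            dz1 = S[0, j] - d * S[3, j]
            dz7 = S[6, j] - d * S[7, j]
            dS[0, j] = S[3, j]
            dS[1, j] = S[4, j]
            dS[2, j] = S[5, j]
            dS[3, j] = a4 * dz9 - S[0, j] / te2 - 2.0 * S[3, j] / te
            dS[4, j] = b5 * dz1 - S[1, j] / te2 - 2.0 * S[4, j] / te
            dS[5, j] = c6 * dz7 - S[2, j] / ti2 - 2.0 * S[5, j] / ti
            dS[6, j] = S[7, j]
            dS[7, j] = d8 * dz9 - S[6, j] / te2 - 2.0 * S[7, j] / te
            dS[8, j] = S[4, j] - S[5, j]

        # explicit parameter dependence J_theta (nonzero rows 3,4,5,7)
        dS[3, 0] += he_te * s9
        dS[3, 4] += a4 * (-x9dot)
        dS[3, 7] += -(he / te2) * (g1 * s9 + u) + 2.0 * x[0] / te3 + 2.0 * x[3] / te2
        dS[3, 8] += (g1 * s9 + u) / te
        dS[3, 9] += he_te

        dS[4, 1] += he_te * s1
        dS[4, 4] += b5 * (-x[3])
        dS[4, 7] += -g2 * he * s1 / te2 + 2.0 * x[1] / te3 + 2.0 * x[4] / te2
        dS[4, 8] += g2 * s1 / te

        dS[5, 3] += hi_ti * s7
        dS[5, 4] += c6 * (-x[7])
        dS[5, 5] += -g4 * hi * s7 / ti2 + 2.0 * x[2] / ti3 + 2.0 * x[5] / ti2
        dS[5, 6] += g4 * s7 / ti

        dS[7, 2] += he_te * s9
        dS[7, 4] += d8 * (-x9dot)
        dS[7, 7] += -g3 * he * s9 / te2 + 2.0 * x[6] / te3 + 2.0 * x[7] / te2
        dS[7, 8] += g3 * s9 / te

        for i in range(9):
            x[i] = x[i] + dt * f[i]
            for j in range(10):
                S[i, j] = S[i, j] + dt * dS[i, j]
        for i in range(9):
            # NaN-safe under fastmath flags: comparison with NaN is False
            if not (abs(x[i]) <= blowup):
                return y, sy, False
        if (k + 1) % ds == 0:
            idx = (k + 1) // ds
            y[idx] = x[8]
            for j in range(10):
                sy[idx, j] = S[8, j]
    return y, sy, True
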
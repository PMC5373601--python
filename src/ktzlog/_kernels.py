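"""Numba-compiled inner loops.

Everything here works on plain float64 scalars/arrays so the kernels stay
cacheable; user-facing wrappers live in :mod:`ktzlog.model`,
:mod:`ktzlog.phases` and :mod:`ktzlog.network`.

Gain codes: 0 = logistic u/(1+|u|), 1 = tanh (argument clamped at +-50 to
avoid overflow in exp).
"""

import numpy as np
from numba import njit

GAIN_LOGISTIC = 0
GAIN_TANH = 1


@njit(cache=True, inline="always")
def _gain(u, gain):
    if gain == GAIN_LOGISTIC:
        return u / (1.0 + abs(u))
    # tanh: clamp to keep exp finite; tanh saturates to +-1 long before 50
    if u > 50.0:
        u = 50.0
    elif u < -50.0:
        u = -50.0
    return np.tanh(u)


@njit(cache=True, inline="always")
def _gain_deriv(u, gain):
    if gain == GAIN_LOGISTIC:
        d = 1.0 + abs(u)
        return 1.0 / (d * d)
    t = _gain(u, GAIN_TANH)
    return 1.0 - t * t


@njit(cache=True)
def iterate(x0, y0, z0, K, T, H, delta, lam, xR, I, discard, n, gain):
    """Advance the map ``discard + n`` steps, recording the last ``n``.

    ``I`` must have length ``discard + n`` (the stimulus applied at every
    step, including discarded ones).  Returns (x, y, z) arrays of length n;
    the first recorded sample is the state after ``discard + 1`` updates.
    """
    x, y, z = x0, y0, z0
    xs = np.empty(n)
    ys = np.empty(n)
    zs = np.empty(n)
    for t in range(discard + n):
        u = (x - K * y + z + H + I[t]) / T
        xn = _gain(u, gain)
        yn = x
        zn = (1.0 - delta) * z - lam * (x - xR)
        x, y, z = xn, yn, zn
        if t >= discard:
            k = t - discard
            xs[k] = x
            ys[k] = y
            zs[k] = z
    return xs, ys, zs


@njit(cache=True)
def advance(x0, y0, z0, K, T, H, delta, lam, xR, I_const, n, gain):
    """n updates under constant input, returning only the final state."""
    x, y, z = x0, y0, z0
    for _ in range(n):
        u = (x - K * y + z + H + I_const) / T
        xn = _gain(u, gain)
        yn = x
        zn = (1.0 - delta) * z - lam * (x - xR)
        x, y, z = xn, yn, zn
    return x, y, z


@njit(cache=True)
def spike_times(xs, threshold, hysteresis):
    """Upward threshold crossings with a re-arm condition.

    A spike is registered when x crosses ``threshold`` upward while armed;
    the detector re-arms only after x has dropped below
    ``threshold - hysteresis``.
    """
    out = np.empty(xs.size, dtype=np.int64)
    m = 0
    armed = xs[0] < threshold - hysteresis
    prev = xs[0]
    for t in range(1, xs.size):
        cur = xs[t]
        if armed and prev < threshold <= cur:
            out[m] = t
            m += 1
            armed = False
        if not armed and cur < threshold - hysteresis:
            armed = True
        prev = cur
    return out[:m]


@njit(cache=True)
def lyapunov_spectrum_caseI(x0, y0, K, T, H, discard, n, renorm, gain):
    """Tangent-space (Eckmann-Ruelle) exponents of the 2-D fast map.

    Propagates an orthonormal 2-frame with the analytic Jacobian,
    re-orthonormalizing (Gram-Schmidt) every ``renorm`` steps.
    """
    x, y = x0, y0
    for _ in range(discard):
        u = (x - K * y + H) / T
        x, y = _gain(u, gain), x
    # frame columns
    v1x, v1y = 1.0, 0.0
    v2x, v2y = 0.0, 1.0
    s1 = 0.0
    s2 = 0.0
    for t in range(n):
        u = (x - K * y + H) / T
        fp = _gain_deriv(u, gain) / T
        a = fp          # dx'/dx
        b = -K * fp     # dx'/dy
        # J = [[a, b], [1, 0]]
        w1x = a * v1x + b * v1y
        w1y = v1x
        w2x = a * v2x + b * v2y
        w2y = v2x
        v1x, v1y, v2x, v2y = w1x, w1y, w2x, w2y
        x, y = _gain(u, gain), x
        if (t + 1) % renorm == 0 or t == n - 1:
            n1 = np.sqrt(v1x * v1x + v1y * v1y)
            s1 += np.log(n1)
            v1x /= n1
            v1y /= n1
            dot = v2x * v1x + v2y * v1y
            v2x -= dot * v1x
            v2y -= dot * v1y
            n2 = np.sqrt(v2x * v2x + v2y * v2y)
            s2 += np.log(n2)
            v2x /= n2
            v2y /= n2
    return s1 / n, s2 / n


@njit(cache=True)
def lyapunov_spectrum_caseII(x0, y0, z0, K, T, H, delta, lam, xR,
                             discard, n, renorm, gain):
    """Eckmann-Ruelle exponent spectrum of the full 3-D map (QR based)."""
    x, y, z = advance(x0, y0, z0, K, T, H, delta, lam, xR, 0.0, discard, gain)
    Q = np.eye(3)
    s = np.zeros(3)
    for t in range(n):
        u = (x - K * y + z + H) / T
        fp = _gain_deriv(u, gain) / T
        J = np.empty((3, 3))
        J[0, 0] = fp
        J[0, 1] = -K * fp
        J[0, 2] = fp
        J[1, 0] = 1.0
        J[1, 1] = 0.0
        J[1, 2] = 0.0
        J[2, 0] = -lam
        J[2, 1] = 0.0
        J[2, 2] = 1.0 - delta
        Q = J @ Q
        xn = _gain(u, gain)
        yn = x
        zn = (1.0 - delta) * z - lam * (x - xR)
        x, y, z = xn, yn, zn
        if (t + 1) % renorm == 0 or t == n - 1:
            Qn, R = np.linalg.qr(Q)
            for i in range(3):
                d = R[i, i]
                s[i] += np.log(abs(d))
                if d < 0.0:
                    for k in range(3):
                        Qn[k, i] = -Qn[k, i]
            Q = Qn
    return s / n


@njit(cache=True)
def occupy_grid(x0, y0, K, T, H, discard, n, m, gain):
    """Mark the boxes of an m x m grid over [-1, 1]^2 visited by the
    (x, y) orbit of the fast subsystem.  Returns the uint8 occupancy grid."""
    grid = np.zeros((m, m), dtype=np.uint8)
    x, y = x0, y0
    for _ in range(discard):
        u = (x - K * y + H) / T
        x, y = _gain(u, gain), x
    for _ in range(n):
        u = (x - K * y + H) / T
        x, y = _gain(u, gain), x
        ix = int((x + 1.0) * 0.5 * m)
        iy = int((y + 1.0) * 0.5 * m)
        if ix >= m:
            ix = m - 1
        if iy >= m:
            iy = m - 1
        grid[ix, iy] = 1
    return grid


@njit(cache=True)
def network_iterate(X0, Y0, Z0, K, T, H, delta, lam, xR, G,
                    topology, I_ext, n, gain):
    """Synchronously advance N gap-junction coupled units for n steps.

    topology: 0 = directed chain (synapse i -> i+1 only),
              1 = complete graph, 2 = undirected chain.
    ``I_ext``: (n, N) external drive added to each unit's input.
    Gap currents use the OLD potentials: I_i = sum_j G (x_j - x_i).
    Returns X record of shape (n, N).
    """
    N = X0.size
    x = X0.copy()
    y = Y0.copy()
    z = Z0.copy()
    xn = np.empty(N)
    yn = np.empty(N)
    zn = np.empty(N)
    rec = np.empty((n, N))
    for t in range(n):
        for i in range(N):
            if topology == 1:
                S = 0.0
                for j in range(N):
                    S += x[j]
                syn = G * (S - N * x[i])
            elif topology == 0:
                syn = G * (x[i - 1] - x[i]) if i > 0 else 0.0
            else:
                syn = 0.0
                if i > 0:
                    syn += G * (x[i - 1] - x[i])
                if i < N - 1:
                    syn += G * (x[i + 1] - x[i])
            u = (x[i] - K * y[i] + z[i] + H + I_ext[t, i] + syn) / T
            xn[i] = _gain(u, gain)
            yn[i] = x[i]
            zn[i] = (1.0 - delta) * z[i] - lam * (x[i] - xR)
        for i in range(N):
            x[i] = xn[i]
            y[i] = yn[i]
            z[i] = zn[i]
            rec[t, i] = x[i]
    return rec
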
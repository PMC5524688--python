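"""Compiled inner loops: Crank-Nicolson stepping and Brownian-dynamics walkers.

Kept free of any Python objects so numba can cache the compiled code.
"""
from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _thomas(al, ad, au, b, x, cp, dp):
    """Solve a tridiagonal system in place (Thomas algorithm).

    al: sub-diagonal (al[0] unused), ad: diagonal, au: super-diagonal
    (au[-1] unused), b: right-hand side. Scratch arrays cp, dp must have
    the same length as b.
    """
    n = ad.shape[0]
    cp[0] = au[0] / ad[0]
    dp[0] = b[0] / ad[0]
    for i in range(1, n):
        m = ad[i] - al[i] * cp[i - 1]
        cp[i] = au[i] / m
        dp[i] = (b[i] - al[i] * dp[i - 1]) / m
    x[n - 1] = dp[n - 1]
    for i in range(n - 2, -1, -1):
        x[i] = dp[i] - cp[i] * x[i + 1]


@njit(cache=True)
def evolve_cn(low, diag, up, x0, dts, weights):
    """TR-BDF2 evolution of dx/dt = L x with tridiagonal L.

    low/diag/up are the diagonals of L (length M; low[0] and up[-1] unused).
    weights is the conservation vector w (w @ L == 0), used to monitor the
    mass-balance defect at every accepted step.  TR-BDF2 is L-stable, so
    the stiff contact-cell mode is damped rather than left oscillating as
    plain Crank-Nicolson would, while remaining second-order accurate and
    exactly conservative (both stages preserve w @ x).

    Returns (times, P, p_contact, mass_err_max, x_final) where P = x[0]
    (bound-state population) and p_contact = x[1] (pair density in the
    first radial cell) recorded after every step, with t = 0 included.
    """
    m = diag.shape[0]
    n_steps = dts.shape[0]
    x = x0.copy()
    xs = np.empty(m)
    xn = np.empty(m)
    b = np.empty(m)
    cp = np.empty(m)
    dp = np.empty(m)
    al = np.empty(m)
    ad = np.empty(m)
    au = np.empty(m)

    gamma = 2.0 - math.sqrt(2.0)
    c_star = 1.0 / (gamma * (2.0 - gamma))
    c_old = (1.0 - gamma) ** 2 / (gamma * (2.0 - gamma))
    beta = (1.0 - gamma) / (2.0 - gamma)

    times = np.empty(n_steps + 1)
    p_bound = np.empty(n_steps + 1)
    p_contact = np.empty(n_steps + 1)
    times[0] = 0.0
    p_bound[0] = x[0]
    p_contact[0] = x[1]

    mass0 = 0.0
    for i in range(m):
        mass0 += weights[i] * x[i]
    mass_err_max = 0.0

    t = 0.0
    for k in range(n_steps):
        dt = dts[k]
        # stage 1: trapezoidal rule over gamma*dt
        h = 0.5 * gamma * dt
        b[0] = x[0] + h * (diag[0] * x[0] + up[0] * x[1])
        for i in range(1, m - 1):
            b[i] = x[i] + h * (low[i] * x[i - 1] + diag[i] * x[i] + up[i] * x[i + 1])
        b[m - 1] = x[m - 1] + h * (low[m - 1] * x[m - 2] + diag[m - 1] * x[m - 1])
        for i in range(m):
            al[i] = -h * low[i]
            ad[i] = 1.0 - h * diag[i]
            au[i] = -h * up[i]
        _thomas(al, ad, au, b, xs, cp, dp)
        # stage 2: BDF2 using x and the intermediate stage
        hb = beta * dt
        for i in range(m):
            b[i] = c_star * xs[i] - c_old * x[i]
            al[i] = -hb * low[i]
            ad[i] = 1.0 - hb * diag[i]
            au[i] = -hb * up[i]
        _thomas(al, ad, au, b, xn, cp, dp)
        for i in range(m):
            x[i] = xn[i]
        t += dt
        times[k + 1] = t
        p_bound[k + 1] = x[0]
        p_contact[k + 1] = x[1]
        mass = 0.0
        for i in range(m):
            mass += weights[i] * x[i]
        err = abs(mass - mass0)
        if err > mass_err_max:
            mass_err_max = err

    return times, p_bound, p_contact, mass_err_max, x


@njit(cache=True)
def brownian_bound_counts(a, r_d, diff, dim, k_pt, k_a, dt, out_times, n_walkers, seed):
    """Count walkers in the bound (ROH*) state at each output time.

    Each walker alternates between an exactly-sampled exponential bound
    dwell (rate k_pt) and Euler-Maruyama radial diffusion in the Coulomb
    field started at contact.  Attempted crossings of r = a are reflected
    specularly and react with the Erban-Chapman probability
    k_a * sqrt(pi dt / diff), which reproduces the radiation boundary to
    leading order in the step size.
    """
    np.random.seed(seed)
    n_t = out_times.shape[0]
    t_end = out_times[n_t - 1]
    counts = np.zeros(n_t, dtype=np.int64)
    p_react = k_a * math.sqrt(math.pi * dt / diff)
    sq = math.sqrt(2.0 * diff * dt)

    for _w in range(n_walkers):
        t = 0.0
        k = 0
        bound = True
        r = a
        while k < n_t:
            if bound:
                if k_pt <= 0.0:
                    t_next = t_end + 1.0
                else:
                    t_next = t + np.random.exponential(1.0 / k_pt)
                while k < n_t and out_times[k] <= t_next:
                    counts[k] += 1
                    k += 1
                if k >= n_t:
                    break
                t = t_next
                r = a
                bound = False
            else:
                t += dt
                drift = diff * dt * ((dim - 1.0) / r - r_d / (r * r))
                r += drift + sq * np.random.normal()
                while r < a:
                    r = 2.0 * a - r
                    if not bound and np.random.random() < p_react:
                        bound = True
                if bound:
                    # state change registered before recording times <= t
                    pass
                while k < n_t and out_times[k] <= t:
                    if bound:
                        counts[k] += 1
                    k += 1
    return counts
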
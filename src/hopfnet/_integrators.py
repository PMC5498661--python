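"""JIT-compiled Euler-Maruyama cores for the Hopf network model.

These functions are deliberately free of Python objects: plain float64
arrays in, arrays plus a blow-up flag out.  Noise is drawn inside the
compiled loop from numpy's legacy RNG seeded per call, which makes every
simulation bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def integrate_network(a, omega, G, offsets, nb_idx, nb_w, beta, dt, n_steps,
                      downsample, transient_steps, seed, x0, y0):
    """Coupled Hopf normal forms with diffusive coupling.

    dx_j = [(a - x_j^2 - y_j^2) x_j - w_j y_j + G sum_i C_ij (x_i - x_j)] dt
           + beta sqrt(dt) N(0,1)
    (and symmetrically for y).  The coupling matrix is passed as per-node
    edge lists (``offsets``/``nb_idx``/``nb_w``, neighbours in ascending
    index order), which skips structural zeros.  Samples x at every
    ``downsample``-th step after ``transient_steps``.

    Returns (out, bad_step): ``bad_step`` >= 0 flags the first step at which
    the state stopped being finite; -1 means success.
    """
    n = omega.shape[0]
    np.random.seed(seed)
    n_keep = (n_steps - transient_steps) // downsample
    out = np.empty((n, n_keep))
    x = x0.copy()
    y = y0.copy()
    xn = np.empty(n)
    yn = np.empty(n)
    sq = beta * np.sqrt(dt)
    kept = 0
    for step in range(n_steps):
        for j in range(n):
            cx = 0.0
            cy = 0.0
            for k in range(offsets[j], offsets[j + 1]):
                i = nb_idx[k]
                w = nb_w[k]
                cx += w * (x[i] - x[j])
                cy += w * (y[i] - y[j])
            r2 = x[j] * x[j] + y[j] * y[j]
            xn[j] = x[j] + dt * ((a - r2) * x[j] - omega[j] * y[j] + G * cx)
            yn[j] = y[j] + dt * ((a - r2) * y[j] + omega[j] * x[j] + G * cy)
        if sq > 0.0:
            for j in range(n):
                xn[j] += sq * np.random.normal()
                yn[j] += sq * np.random.normal()
        tmp = x; x = xn; xn = tmp
        tmp = y; y = yn; yn = tmp
        if step >= transient_steps and (step - transient_steps) % downsample == downsample - 1:
            if kept < n_keep:
                for j in range(n):
                    out[j, kept] = x[j]
                    if not np.isfinite(x[j]):
                        return out, step
                kept += 1
    return out, -1


@njit(cache=True)
def integrate_node(a, omega0, beta, dt, n_steps, seed, x0, y0, f_amp, f_omega):
    """Single forced Hopf node at full resolution.

    Complex forcing F exp(i w_F t) enters the drift additively.  Returns
    (x, y, bad_step) with full-resolution trajectories of length n_steps.
    """
    np.random.seed(seed)
    xs = np.empty(n_steps)
    ys = np.empty(n_steps)
    x = x0
    y = y0
    sq = beta * np.sqrt(dt)
    for step in range(n_steps):
        r2 = x * x + y * y
        t = step * dt
        fx = f_amp * np.cos(f_omega * t)
        fy = f_amp * np.sin(f_omega * t)
        x_new = x + dt * ((a - r2) * x - omega0 * y + fx)
        y_new = y + dt * ((a - r2) * y + omega0 * x + fy)
        if sq > 0.0:
            x_new += sq * np.random.normal()
            y_new += sq * np.random.normal()
        x = x_new
        y = y_new
        xs[step] = x
        ys[step] = y
        if not np.isfinite(x) or not np.isfinite(y):
            return xs, ys, step
    return xs, ys, -1
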
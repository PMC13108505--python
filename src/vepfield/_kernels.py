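"""Tight inner loops for Euler integration and its adjoint sweep.

These are the per-iteration hot paths of MAP optimization: a forward Euler
pass that records the full state tape, and the reverse (adjoint) pass that
accumulates gradients with respect to the initial state, the excitability
map and the global scalars.  Both are JIT-compiled with numba when it is
importable; the same code runs as plain numpy otherwise.

Argument conventions: ``M`` is the dense local-coupling matrix (one
hemisphere grid; both hemispheres share it), sources are ordered
[hemisphere-0 grid, hemisphere-1 grid, subcortical], ``labels`` maps each
source to its region and ``counts`` is the (floored at 1) source count per
region.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every inference test
    from numba import njit

    _jit = njit(cache=True)
except Exception:  # pragma: no cover
    def _jit(f):
        return f


@_jit
def _coupling_terms(x, M, labels, counts, K, Krow, theta, n_grid, n_reg):
    """Sigmoid, homogeneous and long-range coupling terms at state x.

    The dense coupling matmul — the dominant per-step cost — runs in the
    dtype of ``M``; passing a float32 operator roughly halves step time at
    ~1e-7 relative rounding, far below every other error source.
    """
    n = x.shape[0]
    n_cort = 2 * n_grid
    s = 1.0 / (1.0 + np.exp(-(x - theta)))
    hom = np.zeros(n)
    s2 = np.ascontiguousarray(s[:n_cort]).reshape(2, n_grid).astype(M.dtype)
    h2 = s2 @ M.T
    hom[:n_cort] = h2.ravel().astype(np.float64)
    xbar = np.zeros(n_reg)
    for i in range(n):
        xbar[labels[i]] += x[i]
    xbar /= counts
    creg = K @ xbar - Krow * xbar
    lr = np.empty(n)
    for i in range(n):
        lr[i] = creg[labels[i]]
    return s, hom, lr


@_jit
def forward_tape(
    xi, zi, x0, M, labels, counts, K, Krow, G, tau, gamma, theta, I, dt, n_steps
):
    """Euler integration recording state and coupling tapes.

    Besides the state tape (n_steps+1, n), the per-step sigmoid, homogeneous
    and long-range terms (n_steps, n, evaluated at the pre-step state) are
    recorded so the adjoint sweep does not recompute them.
    """
    n = xi.shape[0]
    n_grid = M.shape[0]
    n_reg = counts.shape[0]
    tape_x = np.empty((n_steps + 1, n))
    tape_z = np.empty((n_steps + 1, n))
    tape_s = np.empty((n_steps, n))
    tape_hom = np.empty((n_steps, n))
    tape_lr = np.empty((n_steps, n))
    x = xi.copy()
    z = zi.copy()
    tape_x[0] = x
    tape_z[0] = z
    for t in range(1, n_steps + 1):
        s, hom, lr = _coupling_terms(x, M, labels, counts, K, Krow, theta, n_grid, n_reg)
        tape_s[t - 1] = s
        tape_hom[t - 1] = hom
        tape_lr[t - 1] = lr
        dx = 1.0 - x**3 - 2.0 * x**2 - z + I
        dz = (4.0 * (x - x0) - z - G * lr - gamma * hom) / tau
        x = x + dt * dx
        z = z + dt * dz
        tape_x[t] = x
        tape_z[t] = z
    return tape_x, tape_z, tape_s, tape_hom, tape_lr


@_jit
def adjoint_sweep(
    tape_x,
    tape_z,
    tape_s,
    tape_hom,
    tape_lr,
    g_frames,
    store_every,
    M,
    labels,
    counts,
    K,
    Krow,
    x0,
    G,
    tau,
    gamma,
    theta,
    dt,
):
    """Reverse sweep through the tapes.

    ``g_frames[k]`` is the objective gradient with respect to ``x`` at the
    k-th stored frame (the state after ``store_every * (k + 1)`` steps).
    Returns gradients with respect to the initial ``x``/``z`` maps, the
    ``x0`` map, ``G`` and ``tau``.
    """
    n_steps = tape_x.shape[0] - 1
    n = tape_x.shape[1]
    n_grid = M.shape[0]
    n_cort = 2 * n_grid
    n_reg = counts.shape[0]
    gx = np.zeros(n)
    gz = np.zeros(n)
    g_x0 = np.zeros(n)
    g_G = 0.0
    g_tau = 0.0
    for step in range(n_steps, 0, -1):
        if step % store_every == 0:
            gx = gx + g_frames[step // store_every - 1]
        x_t = tape_x[step - 1]
        z_t = tape_z[step - 1]
        s = tape_s[step - 1]
        hom = tape_hom[step - 1]
        lr = tape_lr[step - 1]
        bracket = 4.0 * (x_t - x0) - z_t - G * lr - gamma * hom

        vz = gz * (dt / tau)
        g_x0 += -4.0 * vz
        for i in range(n):
            g_G -= vz[i] * lr[i]
            g_tau -= gz[i] * (dt / tau**2) * bracket[i]

        gx_new = gx * (1.0 + dt * (-3.0 * x_t**2 - 4.0 * x_t)) + 4.0 * vz
        if G != 0.0:
            t1 = np.zeros(n_reg)
            for i in range(n):
                t1[labels[i]] += vz[i]
            t2 = K.T @ t1 - Krow * t1
            for i in range(n):
                gx_new[i] -= G * t2[labels[i]] / counts[labels[i]]
        v2 = np.ascontiguousarray(vz[:n_cort]).reshape(2, n_grid).astype(M.dtype)
        hadj2 = v2 @ M
        hom_adj = np.zeros(n)
        hom_adj[:n_cort] = hadj2.ravel().astype(np.float64)
        gx_new -= gamma * s * (1.0 - s) * hom_adj
        gz_new = gz * (1.0 - dt / tau) - dt * gx
        gx = gx_new
        gz = gz_new
    return gx, gz, g_x0, g_G, g_tau
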
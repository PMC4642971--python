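"""Compiled adaptive Runge-Kutta integrator for pure mass-action systems.

The Monte-Carlo topology screen integrates tens of thousands of small
mass-action ODE systems; calling a Python right-hand side from LSODA
dominates the runtime there.  This module provides a Dormand-Prince 5(4)
integrator specialized to the compiled (stoichiometry matrix + reactant
index) representation of :class:`~il4redox.reaction.ReactionSystem`,
JIT-compiled with numba.  Output at grid times uses cubic Hermite
interpolation over each accepted step.

The reduced library models are non-stiff over the sampled parameter
ranges; the detailed systems model (external inputs, saturating rate law)
keeps using LSODA via ``ReactionSystem.simulate``.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

STATUS_OK = 0
STATUS_MAXSTEPS = 1
STATUS_NONFINITE = 2

# Dormand-Prince coefficients
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])
_A = np.zeros((7, 7))
_A[1, 0] = 1 / 5
_A[2, :2] = (3 / 40, 9 / 40)
_A[3, :3] = (44 / 45, -56 / 15, 32 / 9)
_A[4, :4] = (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729)
_A[5, :5] = (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656)
_A[6, :6] = (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84)
_B5 = _A[6, :7].copy()
_B4 = np.array([5179 / 57600, 0.0, 7571 / 16695, 393 / 640,
                -92097 / 339200, 187 / 2100, 1 / 40])
_E = _B5 - _B4


@njit(cache=True)
def _mass_action_rhs(y, k, ridx, rptr, N, out):
    ns = N.shape[0]
    nr = k.shape[0]
    for i in range(ns):
        out[i] = 0.0
    for r in range(nr):
        f = k[r]
        for j in range(rptr[r], rptr[r + 1]):
            yi = y[ridx[j]]
            if yi < 0.0:
                yi = 0.0
            f *= yi
        if f != 0.0:
            for i in range(ns):
                nij = N[i, r]
                if nij != 0.0:
                    out[i] += nij * f


@njit(cache=True)
def integrate_mass_action(k, ridx, rptr, N, y0, t_grid, rtol, atol, max_steps,
                          A, C, B5, E):
    """Adaptive RK45 over t_grid span; returns (Y, status)."""
    ns = y0.shape[0]
    nt = t_grid.shape[0]
    Y = np.zeros((nt, ns))
    Y[0] = y0
    t = t_grid[0]
    t_end = t_grid[nt - 1]
    y = y0.copy()
    f0 = np.empty(ns)
    _mass_action_rhs(y, k, ridx, rptr, N, f0)
    K = np.empty((7, ns))
    ytmp = np.empty(ns)
    ynew = np.empty(ns)
    # initial step guess
    h = 1e-3
    grid_pos = 1
    steps = 0
    while t < t_end:
        if steps >= max_steps:
            return Y, STATUS_MAXSTEPS
        if t + h > t_end:
            h = t_end - t
        K[0] = f0
        for s in range(1, 7):
            for i in range(ns):
                acc = 0.0
                for q in range(s):
                    acc += A[s, q] * K[q, i]
                ytmp[i] = y[i] + h * acc
            _mass_action_rhs(ytmp, k, ridx, rptr, N, K[s])
        err = 0.0
        for i in range(ns):
            acc = 0.0
            eacc = 0.0
            for s in range(7):
                acc += B5[s] * K[s, i]
                eacc += E[s] * K[s, i]
            ynew[i] = y[i] + h * acc
            sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
            e = h * eacc / sc
            err += e * e
        err = np.sqrt(err / ns)
        steps += 1
        if not np.isfinite(err):
            return Y, STATUS_NONFINITE
        if err <= 1.0:
            # accepted: fill grid points in (t, t+h] by cubic Hermite
            t_new = t + h
            f1 = K[6]  # FSAL: last stage is rhs at (t+h, ynew)
            while grid_pos < nt and t_grid[grid_pos] <= t_new + 1e-12:
                tau = (t_grid[grid_pos] - t) / h
                h00 = (1 + 2 * tau) * (1 - tau) ** 2
                h10 = tau * (1 - tau) ** 2
                h01 = tau * tau * (3 - 2 * tau)
                h11 = tau * tau * (tau - 1)
                for i in range(ns):
                    Y[grid_pos, i] = (h00 * y[i] + h10 * h * f0[i]
                                      + h01 * ynew[i] + h11 * h * f1[i])
                grid_pos += 1
            t = t_new
            for i in range(ns):
                y[i] = ynew[i]
                f0[i] = f1[i]
            fac = 0.9 * err ** -0.2 if err > 0 else 5.0
        else:
            fac = max(0.9 * err ** -0.2, 0.2)
        if fac > 5.0:
            fac = 5.0
        if fac < 0.2:
            fac = 0.2
        h *= fac
        if h < 1e-12:
            return Y, STATUS_NONFINITE
    return Y, STATUS_OK


def simulate_fast(system, t_grid, parameters=None, y0=None,
                  rtol=1e-6, atol=1e-9, max_steps=200_000):
    """RK45 integration of a pure mass-action ReactionSystem.

    Returns ``(Y, status)`` with status 0 on success.  Systems with
    external inputs or saturating rate laws are rejected.
    """
    if system.inputs or system.saturating:
        raise ValueError("fast path supports pure mass-action systems only")
    N, ridx, rptr, kvec, _, _, _ = system._compile()
    if parameters is not None:
        kvec = system.rate_vector(parameters)
    if y0 is None:
        y0 = system.y0()
    t_grid = np.asarray(t_grid, dtype=float)
    return integrate_mass_action(
        np.asarray(kvec, dtype=float), ridx, rptr, N,
        np.asarray(y0, dtype=float), t_grid, rtol, atol, max_steps,
        _A, _C, _B5, _E)
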
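"""Gram-matrix coordinate descent for l2-regularized lasso subproblems.

Solves ``min_b  w * ||y - X b||^2 + lam * ||b||_1 + (rho/2) * ||b - m||^2``
given the Gram matrix ``G = X^T X`` and correlation vector ``cy = X^T y``.
The running vector ``g = G @ b`` is updated incrementally so a sweep costs
O(p * #changed-coordinates).  Full sweeps alternate with active-set sweeps,
glmnet style.  A numba-jitted kernel is used when numba imports; a pure
numpy twin is the fallback.
"""

from __future__ import annotations

import numpy as np


def _cd_kernel(G, cy, m, w, rho, lam, beta, g, max_sweeps, tol):  # pragma: no cover - jitted twin below
    p = beta.shape[0]
    full_pass = True
    sweeps = 0
    while sweeps < max_sweeps:
        sweeps += 1
        max_delta = 0.0
        for j in range(p):
            if not full_pass and beta[j] == 0.0:
                continue
            denom = 2.0 * w * G[j, j] + rho
            if denom <= 0.0:
                continue
            r = 2.0 * w * (cy[j] - g[j] + G[j, j] * beta[j]) + rho * m[j]
            if r > lam:
                new = (r - lam) / denom
            elif r < -lam:
                new = (r + lam) / denom
            else:
                new = 0.0
            d = new - beta[j]
            if d != 0.0:
                for k in range(p):
                    g[k] += G[j, k] * d
                beta[j] = new
                if abs(d) > max_delta:
                    max_delta = abs(d)
        if full_pass:
            if max_delta < tol:
                return sweeps
            full_pass = False
        elif max_delta < tol:
            full_pass = True
    return sweeps


def _cd_kernel_numpy(G, cy, m, w, rho, lam, beta, g, max_sweeps, tol):
    p = beta.shape[0]
    full_pass = True
    sweeps = 0
    while sweeps < max_sweeps:
        sweeps += 1
        max_delta = 0.0
        idx = range(p) if full_pass else np.nonzero(beta)[0]
        for j in idx:
            denom = 2.0 * w * G[j, j] + rho
            if denom <= 0.0:
                continue
            r = 2.0 * w * (cy[j] - g[j] + G[j, j] * beta[j]) + rho * m[j]
            if r > lam:
                new = (r - lam) / denom
            elif r < -lam:
                new = (r + lam) / denom
            else:
                new = 0.0
            d = new - beta[j]
            if d != 0.0:
                g += G[j] * d
                beta[j] = new
                max_delta = max(max_delta, abs(d))
        if full_pass:
            if max_delta < tol:
                return sweeps
            full_pass = False
        elif max_delta < tol:
            full_pass = True
    return sweeps


try:  # pragma: no cover - import-time dispatch
    from numba import njit

    _cd_kernel = njit(cache=True, fastmath=False)(_cd_kernel)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _cd_kernel = _cd_kernel_numpy
    HAVE_NUMBA = False


def cd_lasso(G, cy, m, w, rho, lam, beta=None, g=None, max_sweeps=1000, tol=1e-8):
    """Run coordinate descent; returns (beta, g, sweeps).  Mutates beta/g in place."""
    p = G.shape[0]
    if beta is None:
        beta = np.zeros(p)
        g = np.zeros(p)
    elif g is None:
        g = G @ beta
    sweeps = _cd_kernel(G, cy, m, w, rho, lam, beta, g, max_sweeps, tol)
    return beta, g, sweeps
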
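"""Batched Nelder-Mead simplex minimisation.

Runs many independent low-dimensional simplex searches in lockstep so
that objective evaluations can be vectorised across problems (voxels x
multistart points).  The update rules and stopping criteria follow the
standard adaptive-free Nelder-Mead algorithm with coefficients
rho = 1 (reflection), chi = 2 (expansion), psi = 0.5 (contraction) and
sigma = 0.5 (shrink), identical to the reference implementation in
scipy.optimize, which serves as the single-problem cross-check in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["nelder_mead_batched", "BatchedNMResult"]

_NONZDELT = 0.05
_ZDELT = 0.00025


@dataclass
class BatchedNMResult:
    x: np.ndarray          # (B, n) minimiser per problem
    fun: np.ndarray        # (B,) objective at minimiser
    converged: np.ndarray  # (B,) bool
    nit: np.ndarray        # (B,) iterations used


def nelder_mead_batched(
    fun: Callable[[np.ndarray, np.ndarray], np.ndarray],
    x0: np.ndarray,
    xatol: float = 1e-8,
    fatol: float = 1e-8,
    maxiter: int = 2000,
) -> BatchedNMResult:
    """Minimise ``fun`` independently for each row of ``x0``.

    Parameters
    ----------
    fun :
        Vectorised objective ``fun(x, idx) -> f`` where ``x`` has shape
        ``(m, n)`` and ``idx`` (shape ``(m,)``) gives the problem index
        of each row, so per-problem data can be gathered.
    x0 :
        Start points, shape ``(B, n)``.
    xatol, fatol :
        Absolute simplex-size and function-spread tolerances; a problem
        converges when both are met.
    maxiter :
        Iteration cap per problem; problems hitting it are flagged
        non-converged but still return their best vertex.
    """
    x0 = np.atleast_2d(np.asarray(x0, dtype=float))
    B, n = x0.shape
    all_idx = np.arange(B)

    # initial simplex: perturb each coordinate by 5% (or a small absolute
    # step at exact zeros)
    sim = np.repeat(x0[:, None, :], n + 1, axis=1)
    for k in range(n):
        y = sim[:, k + 1, k]
        sim[:, k + 1, k] = np.where(y != 0.0, y * (1.0 + _NONZDELT), _ZDELT)

    fsim = np.empty((B, n + 1))
    for j in range(n + 1):
        fsim[:, j] = fun(sim[:, j, :], all_idx)

    def _sort(rows: np.ndarray) -> None:
        order = np.argsort(fsim[rows], axis=1, kind="stable")
        sim[rows] = np.take_along_axis(sim[rows], order[:, :, None], axis=1)
        fsim[rows] = np.take_along_axis(fsim[rows], order, axis=1)

    _sort(all_idx)

    active = np.ones(B, dtype=bool)
    converged = np.zeros(B, dtype=bool)
    nit = np.zeros(B, dtype=int)

    while True:
        act = np.nonzero(active)[0]
        if act.size == 0:
            break
        conv = (
            np.max(np.abs(sim[act, 1:, :] - sim[act, :1, :]), axis=(1, 2)) <= xatol
        ) & (np.max(np.abs(fsim[act, 1:] - fsim[act, :1]), axis=1) <= fatol)
        converged[act[conv]] = True
        active[act[conv]] = False
        act = act[~conv]
        maxed = nit[act] >= maxiter
        active[act[maxed]] = False
        act = act[~maxed]
        if act.size == 0:
            continue
        nit[act] += 1

        xbar = sim[act, :-1, :].mean(axis=1)
        worst = sim[act, -1, :]
        best_f = fsim[act, 0]
        second_f = fsim[act, -2]
        worst_f = fsim[act, -1]

        xr = 2.0 * xbar - worst  # reflection, rho = 1
        fxr = fun(xr, act)
        new_x = xr.copy()
        new_f = fxr.copy()
        shrink = np.zeros(act.size, dtype=bool)

        m_exp = fxr < best_f
        if m_exp.any():
            xe = 3.0 * xbar[m_exp] - 2.0 * worst[m_exp]  # expansion, rho*chi = 2
            fxe = fun(xe, act[m_exp])
            take = fxe < fxr[m_exp]
            new_x[m_exp] = np.where(take[:, None], xe, new_x[m_exp])
            new_f[m_exp] = np.where(take, fxe, new_f[m_exp])

        m_else = ~m_exp & ~(fxr < second_f)
        m_oc = m_else & (fxr < worst_f)  # outside contraction
        if m_oc.any():
            xc = 1.5 * xbar[m_oc] - 0.5 * worst[m_oc]
            fxc = fun(xc, act[m_oc])
            ok = fxc <= fxr[m_oc]
            new_x[m_oc] = np.where(ok[:, None], xc, new_x[m_oc])
            new_f[m_oc] = np.where(ok, fxc, new_f[m_oc])
            shrink[m_oc] = ~ok
        m_ic = m_else & ~m_oc  # inside contraction
        if m_ic.any():
            xcc = 0.5 * xbar[m_ic] + 0.5 * worst[m_ic]
            fxcc = fun(xcc, act[m_ic])
            ok = fxcc < worst_f[m_ic]
            new_x[m_ic] = np.where(ok[:, None], xcc, new_x[m_ic])
            new_f[m_ic] = np.where(ok, fxcc, new_f[m_ic])
            shrink[m_ic] = ~ok

        keep = ~shrink
        rows_keep = act[keep]
        sim[rows_keep, -1, :] = new_x[keep]
        fsim[rows_keep, -1] = new_f[keep]
        if shrink.any():
            rows_sh = act[shrink]
            sim[rows_sh, 1:, :] = sim[rows_sh, :1, :] + 0.5 * (
                sim[rows_sh, 1:, :] - sim[rows_sh, :1, :]
            )
            for j in range(1, n + 1):
                fsim[rows_sh, j] = fun(sim[rows_sh, j, :], rows_sh)
        _sort(act)

    return BatchedNMResult(x=sim[:, 0, :].copy(), fun=fsim[:, 0].copy(),
                           converged=converged, nit=nit)
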
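"""Bound-constrained Nelder-Mead simplex minimization, single and batched.

The leave-one-trial-out procedure solves ``n`` nearly identical optimization
problems (one per left-out unit).  Running them in lockstep lets every
simplex iteration evaluate all still-active problems in one vectorized call,
which is where essentially all of the method's runtime goes.  The per-problem
trajectory is the classic Nelder-Mead recursion with the standard
coefficients (reflection 1, expansion 2, contraction 0.5, shrink 0.5) and is
completely independent of the other problems in the batch, so results are
identical whether problems are solved together or one at a time.

Bounds are enforced by an infinite penalty: candidate vertices outside the
box are scored +inf without being evaluated, so the simplex always stays
feasible and approaches boundary optima from the inside (projection-style
clipping can collapse the simplex onto a face and stall short of an interior
optimum near the bound).  Boundary maximum-likelihood estimates — e.g.
single-trial fits of choice-only models — are reached to within the
convergence tolerance.

Convergence follows ``fminsearch`` semantics: a problem terminates when both
the spread of function values across the simplex and the spread of vertex
coordinates fall below ``fatol`` and ``xatol``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NMResult", "nelder_mead", "nelder_mead_batch"]


@dataclass
class NMResult:
    """Outcome of a (batched) simplex minimization.

    ``x`` has shape ``(P, d)`` and ``f``/``converged``/``n_iter`` have
    shape ``(P,)`` where ``P`` is the number of problems in the batch.
    """

    x: np.ndarray
    f: np.ndarray
    converged: np.ndarray
    n_iter: np.ndarray
    n_eval: int


def _initial_simplex(x0, lower, upper, rel_step, abs_step):
    """Axis-aligned start simplex; steps flip inward at the bounds."""
    P, d = x0.shape
    sim = np.repeat(x0[:, None, :], d + 1, axis=1)
    for k in range(d):
        step = np.where(x0[:, k] != 0.0, rel_step * np.abs(x0[:, k]), abs_step)
        step = np.maximum(step, abs_step)
        cand = x0[:, k] + step
        over = cand > upper[k]
        cand = np.where(over, x0[:, k] - step, cand)
        sim[:, k + 1, k] = np.clip(cand, lower[k], upper[k])
    return sim


def nelder_mead_batch(
    fun,
    x0,
    lower,
    upper,
    *,
    xatol=1e-13,
    fatol=1e-13,
    max_iter=None,
    rel_step=0.05,
    abs_step=0.00025,
):
    """Minimize ``P`` independent ``d``-dimensional objectives in lockstep.

    Parameters
    ----------
    fun
        Callable ``fun(idx, X) -> f`` where ``idx`` is an integer array of
        problem indices, ``X`` the ``(len(idx), d)`` matrix of points (row
        ``r`` belongs to problem ``idx[r]``) and ``f`` the objective values.
    x0
        ``(P, d)`` start points, one per problem.
    lower, upper
        Length-``d`` box bounds shared by all problems.
    """
    x0 = np.atleast_2d(np.asarray(x0, dtype=float))
    P, d = x0.shape
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if max_iter is None:
        max_iter = 200 * d

    x0 = np.clip(x0, lower, upper)
    sim = _initial_simplex(x0, lower, upper, rel_step, abs_step)

    n_eval = 0

    def feval(idx, X):
        """Evaluate feasible rows; infeasible candidates score +inf."""
        nonlocal n_eval
        out = np.full(X.shape[0], np.inf)
        ok = np.all((X >= lower) & (X <= upper), axis=1)
        if ok.any():
            out[ok] = fun(idx[ok], X[ok])
            n_eval += int(ok.sum())
        return out

    all_idx = np.arange(P)
    fsim = np.empty((P, d + 1))
    for v in range(d + 1):
        fsim[:, v] = feval(all_idx, sim[:, v, :])

    converged = np.zeros(P, dtype=bool)
    n_iter = np.zeros(P, dtype=np.int64)

    for _ in range(max_iter):
        order = np.argsort(fsim, axis=1, kind="stable")
        fsim = np.take_along_axis(fsim, order, axis=1)
        sim = np.take_along_axis(sim, order[:, :, None], axis=1)

        f_spread = np.max(np.abs(fsim[:, 1:] - fsim[:, :1]), axis=1)
        x_spread = np.max(np.abs(sim[:, 1:, :] - sim[:, :1, :]), axis=(1, 2))
        converged |= (f_spread <= fatol) & (x_spread <= xatol)
        act = np.flatnonzero(~converged)
        if act.size == 0:
            break
        n_iter[act] += 1

        best = sim[act, 0, :]
        worst = sim[act, -1, :]
        centroid = np.mean(sim[act, :-1, :], axis=1)

        xr = centroid + (centroid - worst)
        fr = feval(act, xr)

        f_best = fsim[act, 0]
        f_second = fsim[act, -2]
        f_worst = fsim[act, -1]

        expand = fr < f_best
        accept_r = (~expand) & (fr < f_second)
        contract_out = (~expand) & (~accept_r) & (fr < f_worst)
        contract_in = (~expand) & (~accept_r) & (~contract_out)

        # Second batched evaluation: each problem needs at most one more point.
        x2 = np.where(
            expand[:, None],
            centroid + 2.0 * (centroid - worst),
            np.where(
                contract_out[:, None],
                centroid + 0.5 * (xr - centroid),
                centroid - 0.5 * (centroid - worst),
            ),
        )
        need2 = ~accept_r
        f2 = np.full(act.size, np.inf)
        idx2 = np.flatnonzero(need2)
        if idx2.size:
            f2[idx2] = feval(act[idx2], x2[idx2])

        new_x = xr.copy()
        new_f = fr.copy()
        # expansion: keep the better of reflected/expanded
        take_e = expand & (f2 < fr)
        new_x[take_e] = x2[take_e]
        new_f[take_e] = f2[take_e]
        # outside contraction accepted if it improves on the reflection
        co_ok = contract_out & (f2 <= fr)
        new_x[co_ok] = x2[co_ok]
        new_f[co_ok] = f2[co_ok]
        # inside contraction accepted if it beats the worst vertex
        ci_ok = contract_in & (f2 < f_worst)
        new_x[ci_ok] = x2[ci_ok]
        new_f[ci_ok] = f2[ci_ok]

        shrink = (contract_out & ~co_ok) | (contract_in & ~ci_ok)
        replace = ~shrink
        rows = act[replace]
        sim[rows, -1, :] = new_x[replace]
        fsim[rows, -1] = new_f[replace]

        srows = act[shrink]
        if srows.size:
            for v in range(1, d + 1):
                pts = best[shrink] + 0.5 * (sim[srows, v, :] - best[shrink])
                sim[srows, v, :] = pts
                fsim[srows, v] = feval(srows, pts)

    order = np.argsort(fsim, axis=1, kind="stable")
    fsim = np.take_along_axis(fsim, order, axis=1)
    sim = np.take_along_axis(sim, order[:, :, None], axis=1)
    return NMResult(
        x=sim[:, 0, :],
        f=fsim[:, 0],
        converged=converged.copy(),
        n_iter=n_iter,
        n_eval=n_eval,
    )


def nelder_mead(fun, x0, lower, upper, **kwargs):
    """Single-problem convenience wrapper around :func:`nelder_mead_batch`."""

    def batched(idx, X):
        return np.array([fun(row) for row in X])

    res = nelder_mead_batch(batched, np.atleast_2d(x0), lower, upper, **kwargs)
    return NMResult(
        x=res.x[0],
        f=res.f[0],
        converged=bool(res.converged[0]),
        n_iter=res.n_iter[0],
        n_eval=res.n_eval,
    )
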
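"""Leave-one-trial-out (LOTO) and the single-trial-fitting baseline.

LOTO turns an ordinary maximum-likelihood fit into per-trial parameter
information: fit the model once to all n trials, then re-estimate the
parameter(s) of interest n times with one unit (trial, block, or item group)
left out, holding every other parameter at its all-trial estimate and
starting each refit from those estimates.  The per-unit delta

    delta_t = theta_hat(all trials) - theta_hat(all trials except t)

is positively related to the unit's true parameter value: an above-average
trial pulls the all-trial estimate up, so removing it lets the estimate drop.
Deltas are relative quantities (above/below the participant's average), not
absolute parameter values — exactly what a trial-wise regressor for neural
data needs.

The n refits are mutually independent; they are solved in lockstep by the
batched simplex, and results are identical to fitting each subset on its
own (order-independent by construction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fitting import FitConfig, ModelFit, fit
from .optimize import nelder_mead_batch

__all__ = [
    "LotoResult",
    "SingleTrialFitResult",
    "RecoveryCorrelations",
    "loto",
    "single_trial_fit",
    "partial_recovery_correlation",
]


@dataclass
class LotoResult:
    """Per-unit LOTO output.

    ``deltas[u, p]`` is the all-trial estimate minus the leave-out estimate
    of free parameter ``p`` for unit ``u``; positive means an above-average
    unit.  ``fit_improvement[u]`` is the deviance improvement on the
    retained trials achieved by re-optimizing after removing ``u`` (the
    statistic of the variability-presence test; non-negative up to
    tolerance by construction).  Degenerate units (structurally
    unidentified leave-out fit) carry NaN deltas and a flag.
    """

    unit_ids: np.ndarray
    param_names: tuple
    deltas: np.ndarray
    leaveout_estimates: np.ndarray
    fit_improvement: np.ndarray
    degenerate: np.ndarray
    all_fit: ModelFit

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    def delta(self, name: str) -> np.ndarray:
        return self.deltas[:, self.param_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        out = {"unit_id": self.unit_ids}
        for i, p in enumerate(self.param_names):
            out[f"delta_{p}"] = self.deltas[:, i]
        for i, p in enumerate(self.param_names):
            out[f"leaveout_{p}"] = self.leaveout_estimates[:, i]
        out["fit_improvement"] = self.fit_improvement
        out["degenerate"] = self.degenerate
        return pd.DataFrame(out)

    def to_csv(self, path) -> None:
        """Write the per-unit table (directly usable as a parametric-
        modulator regressor file)."""
        self.to_frame().to_csv(path, index=False)


@dataclass
class SingleTrialFitResult:
    """Per-trial MLEs of the free parameter(s) with all others fixed."""

    param_names: tuple
    estimates: np.ndarray
    at_bound: np.ndarray
    all_fit: ModelFit

    def estimate(self, name: str) -> np.ndarray:
        return self.estimates[:, self.param_names.index(name)]


def _resolve_units(trials, grouping):
    n = len(trials)
    if grouping is None:
        ids = np.asarray(trials.index)
        units = [np.array([i], dtype=np.int64) for i in range(n)]
        return ids, units
    if isinstance(grouping, str):
        col = np.asarray(trials[grouping])
        ids = pd.unique(col)
        units = [np.flatnonzero(col == g).astype(np.int64) for g in ids]
        return np.asarray(ids), units
    if isinstance(grouping, dict):
        ids = np.asarray(list(grouping.keys()), dtype=object)
        units = [np.asarray(v, dtype=np.int64) for v in grouping.values()]
        return ids, units
    raise TypeError("grouping must be None, a column name, or a dict of index lists")


def loto(model, trials, free: Sequence[str], config: Optional[FitConfig] = None,
         grouping=None, all_fit: Optional[ModelFit] = None) -> LotoResult:
    """Run leave-one-trial-out over a trial table.

    Parameters
    ----------
    model
        A :class:`~loto.models.base.Model`.
    trials
        Trial table (one row per trial).
    free
        Names of the parameter(s) whose trial-wise variability is inferred;
        all are re-estimated jointly in each leave-out fit.
    grouping
        ``None`` for trial-level leave-out, a column name for block-level
        units, or a dict mapping unit ids to positional trial indices
        (units may overlap, as for item-level grouping).
    all_fit
        The all-trial fit from step 1; fitted here when omitted.
    """
    config = config or FitConfig()
    free = tuple(free)
    specs = tuple(model.param_specs())
    names = tuple(model.param_names)
    for f in free:
        if f not in names:
            raise ValueError(f"unknown parameter {f!r}")
    data = model.prepare(trials)
    n = model.n_trials(data)
    if all_fit is None:
        all_fit = fit(model, trials, specs, config)
    unit_ids, units = _resolve_units(trials, grouping)
    if len(units) < 2:
        raise ValueError("LOTO needs at least two units")
    P = len(units)

    free_idx = np.array([names.index(f) for f in free], dtype=np.int64)
    free_mask = np.zeros(len(names), dtype=bool)
    free_mask[free_idx] = True
    template = all_fit.estimates.copy()

    max_m = max(len(u) for u in units)
    excl = np.zeros((P, max_m), dtype=np.int64)
    excl_n = np.zeros(P, dtype=np.int64)
    for p, u in enumerate(units):
        excl[p, : len(u)] = u
        excl_n[p] = len(u)
        if len(u) >= n:
            raise ValueError("a unit may not contain every trial")

    degenerate = model.degenerate_unit_mask(data, units)
    leaveout = np.empty((P, len(free)))
    improvement = np.empty(P)

    closed = model.closed_form_mle(data, free_mask, template)
    if closed is not None:
        # analytic leave-out estimates: exact, no optimizer involved
        ll_all = model.per_trial_loglik(data, all_fit.estimates)
        for p, u in enumerate(units):
            theta_lo = model.closed_form_mle(data, free_mask, template, exclude=u)
            leaveout[p] = theta_lo[free_idx]
            ll_lo = model.per_trial_loglik(data, theta_lo)
            keep = np.ones(n, dtype=bool)
            keep[u] = False
            improvement[p] = -2.0 * (ll_all[keep].sum() - ll_lo[keep].sum())
    else:
        lower = np.array([specs[i].lower for i in free_idx])
        upper = np.array([specs[i].upper for i in free_idx])

        def objective(idx, X):
            thetas = np.repeat(template[None, :], X.shape[0], axis=0)
            thetas[:, free_idx] = X
            return model.deviance_batch(data, thetas, excl[idx], excl_n[idx])

        x0 = np.repeat(template[None, free_idx], P, axis=0)
        dev_start = objective(np.arange(P), x0)
        res = nelder_mead_batch(
            objective, x0, lower, upper,
            xatol=config.xatol, fatol=config.tolerance,
            max_iter=config.max_iterations,
            rel_step=config.refit_rel_step, abs_step=config.refit_abs_step,
        )
        leaveout[:] = res.x
        improvement[:] = dev_start - res.f

    deltas = template[free_idx][None, :] - leaveout
    deltas = deltas.copy()
    deltas[degenerate] = np.nan
    return LotoResult(
        unit_ids=unit_ids,
        param_names=free,
        deltas=deltas,
        leaveout_estimates=leaveout,
        fit_improvement=improvement,
        degenerate=degenerate,
        all_fit=all_fit,
    )


def single_trial_fit(model, trials, free: Sequence[str], config: Optional[FitConfig] = None,
                     all_fit: Optional[ModelFit] = None) -> SingleTrialFitResult:
    """Fit the free parameter(s) to each trial individually.

    The baseline LOTO is compared against: nuisance parameters are fixed to
    the all-trial estimates (which also serve as start values) and the free
    parameters are re-estimated on one trial at a time.  For choice-only
    models the per-trial likelihood is monotone in the parameter, so the
    estimates land on the parameter bounds by construction; they are
    returned as-is with ``at_bound`` flags.
    """
    config = config or FitConfig()
    free = tuple(free)
    specs = tuple(model.param_specs())
    names = tuple(model.param_names)
    data = model.prepare(trials)
    n = model.n_trials(data)
    if all_fit is None:
        all_fit = fit(model, trials, specs, config)

    free_idx = np.array([names.index(f) for f in free], dtype=np.int64)
    template = all_fit.estimates.copy()
    lower = np.array([specs[i].lower for i in free_idx])
    upper = np.array([specs[i].upper for i in free_idx])

    # problem t optimizes the deviance of trial t alone: exclude all others
    excl = np.empty((n, n - 1), dtype=np.int64)
    for t in range(n):
        excl[t, :t] = np.arange(t)
        excl[t, t:] = np.arange(t + 1, n)
    excl_n = np.full(n, n - 1, dtype=np.int64)

    def objective(idx, X):
        thetas = np.repeat(template[None, :], X.shape[0], axis=0)
        thetas[:, free_idx] = X
        return model.deviance_batch(data, thetas, excl[idx], excl_n[idx])

    x0 = np.repeat(template[None, free_idx], n, axis=0)
    res = nelder_mead_batch(
        objective, x0, lower, upper,
        xatol=config.xatol, fatol=config.tolerance,
        max_iter=config.max_iterations,
        rel_step=config.rel_step, abs_step=config.abs_step,
    )
    tol = max(10.0 * config.tolerance, 1e-9)
    at_bound = (np.abs(res.x - lower[None, :]) <= tol) | (np.abs(res.x - upper[None, :]) <= tol)
    return SingleTrialFitResult(
        param_names=free, estimates=res.x, at_bound=at_bound, all_fit=all_fit
    )


@dataclass
class RecoveryCorrelations:
    """Within-stratum Pearson correlations between true trial-wise values
    and their estimates, plus the pooled standardized slope controlling for
    the observations."""

    by_stratum: dict
    flagged: dict
    pooled_slope: float


def partial_recovery_correlation(true_values, estimates, observations) -> RecoveryCorrelations:
    """Correlate estimates with true trial-wise values within observation
    strata (e.g. separately for immediate and delayed choices).

    The stratification removes the information already carried by the
    observation itself; the pooled slope is the standardized regression
    coefficient of the true values when the observation columns are
    partialled out.  Strata with fewer than 3 trials or zero variance are
    flagged and reported as NaN.
    """
    true_values = np.asarray(true_values, dtype=float)
    estimates = np.asarray(estimates, dtype=float)
    obs = np.asarray(observations)
    if obs.ndim == 1:
        obs = obs[:, None]
    strata = obs[:, 0]
    ok = np.isfinite(true_values) & np.isfinite(estimates)

    by_stratum, flagged = {}, {}
    for s in np.unique(strata):
        m = (strata == s) & ok
        if m.sum() < 3 or np.std(estimates[m]) == 0 or np.std(true_values[m]) == 0:
            by_stratum[s] = np.nan
            flagged[s] = True
            continue
        by_stratum[s] = float(np.corrcoef(true_values[m], estimates[m])[0, 1])
        flagged[s] = False

    def z(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    X = np.column_stack(
        [np.ones(ok.sum()), z(true_values[ok])] + [z(obs[ok, c].astype(float)) for c in range(obs.shape[1])]
    )
    coef, *_ = np.linalg.lstsq(X, z(estimates[ok]), rcond=None)
    return RecoveryCorrelations(by_stratum=by_stratum, flagged=flagged, pooled_slope=float(coef[1]))
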
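"""Hyperbolic discounting (HD) model of intertemporal choice.

An option paying amount ``x`` after delay ``d`` (days) has utility
``u = x / (1 + kappa * d)`` with discount rate κ ∈ [0, 1].  Choice
probabilities come from the softmax rule with sensitivity β ≥ 0; for two
options this is the logistic function of β(u_i - u_j).

Because the single-choice log-likelihood is monotone in κ (always increasing
after an immediate choice, always decreasing after a delayed choice), κ is
only interior-identified once both options have been chosen; the analytic
MLE for a repeated trial chosen ``n_i``/``n_j`` times is available in
:func:`hd_kappa_closed_form`.

Trial table columns: ``x_i, d_i`` (first/immediate option), ``x_j, d_j``
(second/delayed option), optionally ``x_k, d_k`` for three-option tasks;
``choice`` is the 0-based index of the chosen option (0 = immediate).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional

import numpy as np
from scipy.special import logsumexp

from ..fitting import DegenerateEstimateError, ParameterSpec
from .base import LOG_FLOOR, Model
from ._kernels import hd_deviance_batch

__all__ = [
    "HDParams",
    "IntertemporalTrial",
    "hd_utility",
    "softmax_choice_prob",
    "hd_loglik",
    "hd_score_kappa",
    "hd_kappa_closed_form",
    "HDModel",
]


@dataclass(frozen=True)
class HDParams:
    """Discount rate κ ∈ [0, 1] and softmax sensitivity β ≥ 0."""

    kappa: float
    beta: float

    def __post_init__(self):
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")
        if self.beta < 0.0:
            raise ValueError("beta must be >= 0")


@dataclass(frozen=True)
class IntertemporalTrial:
    """One choice between an immediate and a delayed reward (amounts in
    currency units, delays in days)."""

    x_i: float
    x_j: float
    d_j: float
    d_i: float = 0.0

    def __post_init__(self):
        if self.x_i <= 0 or self.x_j <= 0:
            raise ValueError("amounts must be positive")
        if self.d_i < 0 or self.d_j <= 0:
            raise ValueError("need d_i >= 0 and d_j > 0")


def hd_utility(x, d, kappa):
    """Hyperbolically discounted utility x / (1 + κ d)."""
    return np.asarray(x, dtype=float) / (1.0 + kappa * np.asarray(d, dtype=float))


def softmax_choice_prob(utilities, beta):
    """Softmax choice probabilities over a utility vector.

    Overflow-safe (shifts by the maximum logit); β = 0 yields the uniform
    distribution.  The two-option case reduces to the logistic function of
    β(u_1 - u_2).
    """
    z = beta * np.asarray(utilities, dtype=float)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class _HDData(NamedTuple):
    amounts: np.ndarray  # (n, K)
    delays: np.ndarray  # (n, K)
    choice: np.ndarray  # (n,)


class HDModel(Model):
    """Hyperbolic discounting + softmax over a two- or three-option table."""

    name = "hd"
    choice_column = "choice"

    def param_specs(self):
        # grid ranges span the empirically plausible region (discount rates
        # above ~0.1/day are rare); the bounds stay at the formal limits
        return (
            ParameterSpec("kappa", 0.0, 1.0, grid_points=25, grid_upper=0.1),
            ParameterSpec("beta", 0.0, 10.0, grid_points=25, grid_lower=0.01),
        )

    def prepare(self, trials):
        cols = [("x_i", "d_i"), ("x_j", "d_j")]
        if "x_k" in trials.columns:
            cols.append(("x_k", "d_k"))
        amounts = np.column_stack([np.asarray(trials[a], dtype=float) for a, _ in cols])
        delays = np.column_stack([np.asarray(trials[d], dtype=float) for _, d in cols])
        choice = np.asarray(trials["choice"], dtype=np.int64)
        return _HDData(amounts, delays, choice)

    def n_trials(self, data):
        return int(data.choice.shape[0])

    def per_trial_loglik(self, data, theta):
        kappa, beta = float(theta[0]), float(theta[1])
        logits = beta * data.amounts / (1.0 + kappa * data.delays)
        lp = logits - logsumexp(logits, axis=1, keepdims=True)
        ll = lp[np.arange(lp.shape[0]), data.choice]
        return np.maximum(ll, LOG_FLOOR)

    def deviance_batch(self, data, thetas, excl=None, excl_n=None):
        thetas = np.ascontiguousarray(np.atleast_2d(thetas), dtype=float)
        P = thetas.shape[0]
        if excl is None:
            excl = np.zeros((P, 1), dtype=np.int64)
            excl_n = np.zeros(P, dtype=np.int64)
        out = np.empty(P)
        hd_deviance_batch(
            data.amounts, data.delays, data.choice, thetas,
            np.ascontiguousarray(excl, dtype=np.int64),
            np.ascontiguousarray(excl_n, dtype=np.int64), out,
        )
        return out

    def simulate(self, trials, theta, rng, utility_noise=None):
        """Sample choices from the softmax; ``utility_noise`` (n, K) is an
        additive perturbation of the utilities at generation time only."""
        th = self.theta_matrix(theta, len(trials))
        U = np.column_stack(
            [
                trials[a].to_numpy(dtype=float) / (1.0 + th[:, 0] * trials[d].to_numpy(dtype=float))
                for a, d in (
                    [("x_i", "d_i"), ("x_j", "d_j"), ("x_k", "d_k")]
                    if "x_k" in trials.columns
                    else [("x_i", "d_i"), ("x_j", "d_j")]
                )
            ]
        )
        if utility_noise is not None:
            U = U + utility_noise
        P = softmax_choice_prob(U, th[:, 1:2])
        cum = np.cumsum(P, axis=1)
        draws = rng.random(len(trials))
        choice = (draws[:, None] > cum).sum(axis=1)
        out = trials.copy()
        out["choice"] = choice.astype(np.int64)
        return out

    def degenerate_unit_mask(self, data, units):
        """A unit is degenerate when removing it leaves some chosen option
        with zero remaining choices (the closed-form estimate then escapes
        the admissible range)."""
        n_opt = data.amounts.shape[1]
        totals = np.bincount(data.choice, minlength=n_opt)
        mask = np.zeros(len(units), dtype=bool)
        for u, idx in enumerate(units):
            counts = np.bincount(data.choice[idx], minlength=n_opt)
            mask[u] = bool(np.any((totals >= 1) & (totals - counts == 0)))
        return mask

    def subset_is_degenerate(self, data):
        n_opt = data.amounts.shape[1]
        totals = np.bincount(data.choice, minlength=n_opt)
        return bool((totals == 0).any())


def hd_loglik(trials, params: HDParams) -> float:
    """Total log-likelihood of a trial table under the HD model."""
    model = HDModel()
    data = model.prepare(trials)
    return float(model.per_trial_loglik(data, np.array([params.kappa, params.beta])).sum())


def hd_score_kappa(trial: IntertemporalTrial, choice: int, params: HDParams) -> float:
    """Analytic derivative of the single-trial log-likelihood w.r.t. κ.

    Positive whenever the immediate option was chosen and negative whenever
    the delayed option was chosen — the reason choice-only single-trial
    estimates of κ always sit on a parameter bound.
    """
    from scipy.special import expit

    k, b = params.kappa, params.beta
    u_i = trial.x_i / (1.0 + k * trial.d_i)
    u_j = trial.x_j / (1.0 + k * trial.d_j)
    # du/dkappa for each option
    g_i = -trial.x_i * trial.d_i / (1.0 + k * trial.d_i) ** 2
    g_j = -trial.x_j * trial.d_j / (1.0 + k * trial.d_j) ** 2
    if choice == 0:
        # 1 - p_i evaluated directly so the sign survives when p_i -> 1
        return float(b * (g_i - g_j) * expit(-b * (u_i - u_j)))
    return float(-b * (g_i - g_j) * expit(b * (u_i - u_j)))


def hd_kappa_closed_form(trial: IntertemporalTrial, n_i: int, n_j: int, beta: float) -> float:
    """Analytic MLE of κ for one trial repeated with ``n_i`` immediate and
    ``n_j`` delayed choices.

    κ = (1/d_j) * (β x_j / (β x_i + ln(n_j/n_i)) - 1); with equal counts this
    collapses to (x_j - x_i)/(d_j x_i).  Requires both options chosen at
    least once — otherwise the estimate escapes the admissible range and a
    :class:`DegenerateEstimateError` is raised.  The returned value is the
    raw root of the score; numerical estimation clamps to the [0, 1] bounds.
    """
    if n_i < 1 or n_j < 1:
        raise DegenerateEstimateError("closed-form kappa needs n_i >= 1 and n_j >= 1")
    if trial.d_i != 0.0:
        raise ValueError("closed form assumes an immediate first option (d_i = 0)")
    denom = beta * trial.x_i + np.log(n_j / n_i)
    if denom <= 0:
        raise DegenerateEstimateError("score has no admissible root for these counts")
    return float((beta * trial.x_j / denom - 1.0) / trial.d_j)
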
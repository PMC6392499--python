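"""Bernoulli/binomial toy model.

The simplest setting in which the leave-one-out logic can be written down in
closed form: ``n`` Bernoulli trials with success probability θ, optionally
grouped into blocks of ``m`` trials over which θ is assumed constant.  The
MLE is k/n, the leave-one-unit-out estimate is (k - k_unit)/(n - m), and
their difference — the per-unit estimate of above/below-average θ — is
linear in the unit's success count with slope 1/(n - m).

Trial table columns: ``success`` (0/1) and optionally ``unit_id`` (block
key for the grouped variant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..fitting import ParameterSpec
from .base import LOG_FLOOR, Model

__all__ = [
    "BinomialData",
    "binom_mle",
    "loto_binomial",
    "fisher_info_binomial",
    "BinomialModel",
]


@dataclass(frozen=True)
class BinomialData:
    """Aggregate counts: ``k`` successes out of ``n`` trials."""

    k: int
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.k <= self.n:
            raise ValueError("need 0 <= k <= n")


def binom_mle(data: BinomialData) -> float:
    """Maximum-likelihood estimate of the success probability: k/n."""
    return data.k / data.n


def loto_binomial(data: BinomialData, k_unit: int, m: int = 1) -> float:
    """Closed-form leave-one-unit-out delta: k/n - (k - k_unit)/(n - m).

    ``k_unit`` is the success count of the left-out unit of ``m`` trials
    (``m = 1`` recovers the single-trial case).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if data.n <= m:
        raise ValueError("need n > m to leave a unit out")
    if not 0 <= k_unit <= min(m, data.k):
        raise ValueError("need 0 <= k_unit <= min(m, k)")
    return data.k / data.n - (data.k - k_unit) / (data.n - m)


def fisher_info_binomial(theta: float, m: int = 1) -> float:
    """Fisher information m / (θ(1-θ)); infinite at the boundary.

    The information is U-shaped with its minimum at θ = 0.5: observations
    are most informative about extreme success probabilities.  θ of exactly
    0 or 1 returns ``inf`` (the documented sentinel).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 <= theta <= 1.0:
        raise ValueError("theta must lie in [0, 1]")
    if theta in (0.0, 1.0):
        return float("inf")
    return m / (theta * (1.0 - theta))


class BinomialModel(Model):
    """Bernoulli likelihood over a ``success`` column; analytic MLE."""

    name = "binomial"
    choice_column = "success"

    def param_specs(self):
        return (ParameterSpec("theta", 0.0, 1.0, grid_points=25),)

    def prepare(self, trials):
        return np.asarray(trials["success"], dtype=np.int64)

    def n_trials(self, data):
        return int(data.shape[0])

    def per_trial_loglik(self, data, theta):
        th = float(np.asarray(theta).ravel()[0])
        ll = np.where(data == 1, np.log(max(th, 1e-300)), np.log(max(1.0 - th, 1e-300)))
        return np.maximum(ll, LOG_FLOOR)

    def closed_form_mle(self, data, free, template, exclude=None):
        if not free[0]:
            return None
        if exclude is not None and len(exclude) > 0:
            mask = np.ones(data.shape[0], dtype=bool)
            mask[np.asarray(exclude, dtype=np.int64)] = False
            sub = data[mask]
        else:
            sub = data
        if sub.size == 0:
            raise ValueError("cannot estimate theta from zero trials")
        return np.array([sub.sum() / sub.size], dtype=float)

    def simulate(self, trials, theta, rng):
        n = len(trials)
        th = self.theta_matrix(theta, n)[:, 0]
        out = trials.copy()
        out["success"] = (rng.random(n) < th).astype(np.int64)
        return out

    @staticmethod
    def from_counts(k: int, n: int, success_first: bool = True) -> pd.DataFrame:
        """Build a trial table with ``k`` successes in ``n`` trials.

        With ``success_first`` the first trial is a success and the second a
        failure (when both exist), matching the worked example layout.
        """
        BinomialData(k, n)
        succ = np.zeros(n, dtype=np.int64)
        if not success_first:
            succ[:k] = 1
        elif 2 * k <= n:
            succ[0 : 2 * k : 2] = 1  # successes on even trials: trial 0 success, trial 1 failure
        else:
            succ[:] = 1
            succ[1 : 2 * (n - k) : 2] = 0
        return pd.DataFrame({"success": succ, "unit_id": np.arange(n)})
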
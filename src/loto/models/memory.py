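"""Memory-based decision model (unbounded diffusion with recall probability).

Choices between two remembered options are modeled as an unbounded diffusion
over a fixed deliberation window of t seconds (a design variable, not a
response time): the probability of choosing the left option is

    p(left) = Phi(Delta_V * t / sigma),
    Delta_V = M_l (V_l - g) - M_r (V_r - g),

where V are standardized subjective values, M is the probability that the
option was remembered (alpha for items encoded once, beta_mem for items
encoded twice), g is the per-subject memory bias (an input constant,
estimated elsewhere), and sigma is the diffusion noise.  Longer deliberation
makes decisions more value-consistent.

Trial table columns: ``V_l, V_r`` (standardized values), ``enc_l, enc_r``
(1 or 2 encoding presentations), ``g`` (per-subject constant), ``t_delib``
(seconds), ``choice`` (0 = left), optional ``item_l, item_r`` item keys for
item-level leave-out grouping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.stats import norm

from ..fitting import ParameterSpec
from .base import LOG_FLOOR, Model

__all__ = ["MemoryModelParams", "memory_choice_prob", "MemoryModel", "item_groups"]


@dataclass(frozen=True)
class MemoryModelParams:
    """sigma: diffusion noise; alpha/beta_mem: recall probabilities for
    once/twice-encoded items; g: memory bias (fixed per subject)."""

    sigma: float
    alpha: float
    beta_mem: float
    g: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0 <= self.alpha <= 1 and 0 <= self.beta_mem <= 1):
            raise ValueError("memory probabilities must lie in [0, 1]")


def memory_choice_prob(V_l, V_r, M_l, M_r, g, t, sigma):
    """P(choose left) = Phi(Delta_V * t / sigma).

    sigma = 0 is the noiseless limit: a step function of Delta_V (0.5 at a
    tie).
    """
    dv = M_l * (np.asarray(V_l, dtype=float) - g) - M_r * (np.asarray(V_r, dtype=float) - g)
    if sigma == 0:
        return np.where(dv > 0, 1.0, np.where(dv < 0, 0.0, 0.5))
    return norm.cdf(dv * t / sigma)


class _MemData(NamedTuple):
    V_l: np.ndarray
    V_r: np.ndarray
    enc_l: np.ndarray
    enc_r: np.ndarray
    g: np.ndarray
    t: np.ndarray
    choice: np.ndarray


class MemoryModel(Model):
    """Likelihood over (sigma, alpha, beta_mem); g comes from the table."""

    name = "memory"
    choice_column = "choice"

    def param_specs(self):
        return (
            ParameterSpec("sigma", 0.01, 10.0, grid_points=10),
            ParameterSpec("alpha", 0.0, 1.0, grid_points=10),
            ParameterSpec("beta_mem", 0.0, 1.0, grid_points=10),
        )

    def prepare(self, trials):
        return _MemData(
            np.asarray(trials["V_l"], dtype=float),
            np.asarray(trials["V_r"], dtype=float),
            np.asarray(trials["enc_l"], dtype=np.int64),
            np.asarray(trials["enc_r"], dtype=np.int64),
            np.asarray(trials["g"], dtype=float),
            np.asarray(trials["t_delib"], dtype=float),
            np.asarray(trials["choice"], dtype=np.int64),
        )

    def n_trials(self, data):
        return int(data.choice.shape[0])

    def _p_left(self, data, theta):
        sigma, alpha, beta_mem = (float(v) for v in theta)
        M_l = np.where(data.enc_l == 1, alpha, beta_mem)
        M_r = np.where(data.enc_r == 1, alpha, beta_mem)
        dv = M_l * (data.V_l - data.g) - M_r * (data.V_r - data.g)
        if sigma == 0:
            return np.where(dv > 0, 1.0, np.where(dv < 0, 0.0, 0.5))
        return norm.cdf(dv * data.t / sigma)

    def per_trial_loglik(self, data, theta):
        p_left = self._p_left(data, theta)
        p = np.where(data.choice == 0, p_left, 1.0 - p_left)
        return np.maximum(np.log(np.maximum(p, 1e-300)), LOG_FLOOR)

    def simulate(self, trials, theta, rng):
        data = self.prepare(trials)
        th = self.theta_matrix(theta, len(trials))
        p_left = np.array(
            [self._p_left(_MemData(*[a[t : t + 1] for a in data]), th[t])[0] for t in range(len(trials))]
        )
        out = trials.copy()
        out["choice"] = (rng.random(len(trials)) >= p_left).astype(np.int64)
        return out


def item_groups(trials) -> dict:
    """Map each item key to the positional indices of the trials that offer
    it as either option — the grouping for item-level leave-out."""
    groups: dict = {}
    for pos, (il, ir) in enumerate(zip(trials["item_l"], trials["item_r"])):
        groups.setdefault(il, []).append(pos)
        groups.setdefault(ir, []).append(pos)
    return {k: np.asarray(v, dtype=np.int64) for k, v in sorted(groups.items(), key=lambda kv: str(kv[0]))}
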
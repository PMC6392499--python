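"""Hyperbolic discounting with an LBA response process (HD-LBA).

Replaces the softmax of the choice-only HD model with a linear ballistic
accumulator so that the model predicts choices and response times jointly.
The utility difference maps onto the accumulators' expected drift rates as

    v_i = 1/2 + lambda * (u_i - u_j),      v_j = 1 - v_i,

which keeps the two expected drifts summing to one.  Because a hard
decision (small |u_i - u_j|) slows responses, RTs carry information about
the trial's discount rate over and above the choice itself — the reason
leave-one-trial-out recovers κ far better under HD-LBA than under HD.

Trial table columns: ``x_i, d_i, x_j, d_j`` as in the HD model plus
``choice`` (0 = immediate) and ``rt`` (seconds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from ..fitting import ParameterSpec
from .base import LOG_FLOOR, Model
from ._kernels import hdlba_deviance_batch
from .lba import sample_lba_trials
from scipy.stats import norm

__all__ = ["HDLBAParams", "hdlba_drift_means", "HDLBAModel"]


@dataclass(frozen=True)
class HDLBAParams:
    """κ: discount rate; λ: utility-to-drift scaling; s, b, A, t0 as in the
    LBA."""

    kappa: float
    lambda_: float
    s: float
    b: float
    A: float
    t0: float

    def __post_init__(self):
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be > 0")
        if self.s <= 0 or self.A <= 0 or self.b < self.A or self.t0 < 0:
            raise ValueError("need s > 0, A > 0, b >= A, t0 >= 0")


def hdlba_drift_means(u_i, u_j, lambda_):
    """Map a utility difference onto expected drift rates summing to one."""
    v_i = 0.5 + lambda_ * (np.asarray(u_i, dtype=float) - np.asarray(u_j, dtype=float))
    return v_i, 1.0 - v_i


def _pdf_vec(dt, v, s, b, A):
    """LBA first-passage density with per-trial drift means (array v)."""
    out = np.zeros_like(dt)
    pos = dt > 0
    t, vv = dt[pos], v[pos]
    ts = t * s
    z1 = (b - A - t * vv) / ts
    z2 = (b - t * vv) / ts
    f = (-vv * norm.cdf(z1) + s * norm.pdf(z1) + vv * norm.cdf(z2) - s * norm.pdf(z2)) / A
    out[pos] = np.maximum(f, 0.0)
    return out


def _cdf_vec(dt, v, s, b, A):
    out = np.zeros_like(dt)
    pos = dt > 0
    t, vv = dt[pos], v[pos]
    ts = t * s
    z1 = (b - A - t * vv) / ts
    z2 = (b - t * vv) / ts
    F = (
        1.0
        + (b - A - t * vv) / A * norm.cdf(z1)
        - (b - t * vv) / A * norm.cdf(z2)
        + ts / A * norm.pdf(z1)
        - ts / A * norm.pdf(z2)
    )
    out[pos] = np.clip(F, 0.0, 1.0)
    return out


class _HDLBAData(NamedTuple):
    x_i: np.ndarray
    d_i: np.ndarray
    x_j: np.ndarray
    d_j: np.ndarray
    choice: np.ndarray
    rt: np.ndarray


class HDLBAModel(Model):
    """Joint choice/RT likelihood for intertemporal choice."""

    name = "hdlba"
    choice_column = "choice"

    def param_specs(self):
        # extensive grids for the participant-varying parameters (kappa, b),
        # coarse 3-point grids for the shared nuisance parameters
        return (
            ParameterSpec("kappa", 0.0, 1.0, grid_points=15, grid_upper=0.1),
            ParameterSpec("lambda_", 0.001, 1.0, grid_points=3, grid_upper=0.3),
            ParameterSpec("s", 0.05, 1.5, grid_points=3, grid_upper=0.6),
            ParameterSpec("b", 1.0, 5.0, grid_points=15, grid_lower=1.5, grid_upper=3.5),
            ParameterSpec("A", 0.1, 3.0, grid_points=3, grid_upper=1.5),
            ParameterSpec("t0", 0.01, 1.5, grid_points=3, grid_upper=0.8),
        )

    def prepare(self, trials):
        return _HDLBAData(
            np.asarray(trials["x_i"], dtype=float),
            np.asarray(trials["d_i"], dtype=float),
            np.asarray(trials["x_j"], dtype=float),
            np.asarray(trials["d_j"], dtype=float),
            np.asarray(trials["choice"], dtype=np.int64),
            np.asarray(trials["rt"], dtype=float),
        )

    def n_trials(self, data):
        return int(data.choice.shape[0])

    def per_trial_loglik(self, data, theta):
        kappa, lam, s, b, A, t0 = (float(v) for v in theta)
        if b < A or s <= 0:
            return np.full(data.rt.shape[0], LOG_FLOOR)
        u_i = data.x_i / (1.0 + kappa * data.d_i)
        u_j = data.x_j / (1.0 + kappa * data.d_j)
        v0 = 0.5 + lam * (u_i - u_j)
        v1 = 1.0 - v0
        dt = data.rt - t0
        win = np.where(data.choice == 0, v0, v1)
        lose = np.where(data.choice == 0, v1, v0)
        g = _pdf_vec(dt, win, s, b, A) * (1.0 - _cdf_vec(dt, lose, s, b, A))
        denom = 1.0 - norm.cdf(-v0 / s) * norm.cdf(-v1 / s)
        g = np.where(denom < 1e-10, 0.0, g / np.maximum(denom, 1e-10))
        return np.maximum(np.log(np.maximum(g, 1e-300)), LOG_FLOOR)

    def deviance_batch(self, data, thetas, excl=None, excl_n=None):
        thetas = np.ascontiguousarray(np.atleast_2d(thetas), dtype=float)
        P = thetas.shape[0]
        if excl is None:
            excl = np.zeros((P, 1), dtype=np.int64)
            excl_n = np.zeros(P, dtype=np.int64)
        out = np.empty(P)
        hdlba_deviance_batch(
            data.x_i, data.d_i, data.x_j, data.d_j, data.choice, data.rt, thetas,
            np.ascontiguousarray(excl, dtype=np.int64),
            np.ascontiguousarray(excl_n, dtype=np.int64), out,
        )
        return out

    def simulate(self, trials, theta, rng):
        th = self.theta_matrix(theta, len(trials))
        kappa = th[:, 0]
        u_i = trials["x_i"].to_numpy(dtype=float) / (1.0 + kappa * trials["d_i"].to_numpy(dtype=float))
        u_j = trials["x_j"].to_numpy(dtype=float) / (1.0 + kappa * trials["d_j"].to_numpy(dtype=float))
        v0, v1 = hdlba_drift_means(u_i, u_j, th[:, 1])
        choice, rt, _, _ = sample_lba_trials(
            np.column_stack([v0, v1]), float(th[0, 2]), th[:, 3], th[:, 4], th[:, 5], rng
        )
        out = trials.copy()
        out["choice"] = choice
        out["rt"] = rt
        return out
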
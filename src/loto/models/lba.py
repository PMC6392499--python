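"""Linear ballistic accumulator (LBA) with two accumulators.

Each accumulator starts at a point drawn uniformly from [0, A], accumulates
evidence linearly at a rate drawn from N(v_k, s), and the first to reach the
threshold b determines the response; the response time is the crossing time
plus the non-decision time t0.  The joint choice/RT density is the standard
defective density: the winner's first-passage density times the probability
that the loser has not yet finished.

Trials on which every sampled drift is non-positive are resampled in the
simulator (no accumulator would ever finish); the density is correspondingly
normalized by 1 - P(all drifts <= 0) so that it integrates to one over both
responses.  Drift means follow the sum-to-one convention (v, 1 - v).

Trial table columns: ``choice`` (0 = first/correct accumulator) and ``rt``
(seconds).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy.stats import norm

from ..fitting import ParameterSpec
from .base import LOG_FLOOR, Model
from ._kernels import lba_deviance_batch

__all__ = [
    "LBAParams",
    "lba_pdf",
    "lba_cdf",
    "lba_defective_density",
    "sample_lba_trials",
    "LBAModel",
]


@dataclass(frozen=True)
class LBAParams:
    """nu: mean drift of the first (correct) accumulator; s: drift SD;
    b: decision threshold; A: start-point range; t0: non-decision time (s)."""

    nu: float
    s: float
    b: float
    A: float
    t0: float

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("s must be > 0")
        if self.A <= 0:
            raise ValueError("A must be > 0")
        if self.b < self.A:
            raise ValueError("threshold b must be >= A")
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")


def lba_cdf(t, v, s, b, A):
    """P(single accumulator crosses b within decision time t)."""
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    if tp.size:
        if A < 1e-10:
            out[pos] = norm.cdf((v - b / tp) / s)
        else:
            ts = tp * s
            z1 = (b - A - tp * v) / ts
            z2 = (b - tp * v) / ts
            F = (
                1.0
                + (b - A - tp * v) / A * norm.cdf(z1)
                - (b - tp * v) / A * norm.cdf(z2)
                + ts / A * norm.pdf(z1)
                - ts / A * norm.pdf(z2)
            )
            out[pos] = np.clip(F, 0.0, 1.0)
    return float(out[0]) if scalar else out


def lba_pdf(t, v, s, b, A):
    """First-passage density of a single accumulator at decision time t."""
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    if tp.size:
        if A < 1e-10:
            out[pos] = (b / tp**2) * norm.pdf((b / tp - v) / s) / s
        else:
            ts = tp * s
            z1 = (b - A - tp * v) / ts
            z2 = (b - tp * v) / ts
            f = (-v * norm.cdf(z1) + s * norm.pdf(z1) + v * norm.cdf(z2) - s * norm.pdf(z2)) / A
            out[pos] = np.maximum(f, 0.0)
    return float(out[0]) if scalar else out


def lba_defective_density(t, choice, params: LBAParams, drifts, normalize=True):
    """Joint density of (choice, RT = t): winner's first-passage density at
    t - t0 times the loser's survival, conditioned on at least one positive
    sampled drift when ``normalize`` is set."""
    drifts = np.asarray(drifts, dtype=float)
    dt = np.asarray(t, dtype=float) - params.t0
    win = drifts[choice]
    lose = drifts[1 - choice]
    g = lba_pdf(dt, win, params.s, params.b, params.A) * (
        1.0 - lba_cdf(dt, lose, params.s, params.b, params.A)
    )
    if normalize:
        p_none = float(norm.cdf(-drifts[0] / params.s) * norm.cdf(-drifts[1] / params.s))
        g = g / (1.0 - p_none)
    return g


def sample_lba_trials(drift_means, s, b, A, t0, rng):
    """Simulate choices and RTs for per-trial drift means ``(n, 2)``.

    ``b``, ``A``, ``t0`` may be scalars or per-trial arrays.  Trials where
    both sampled drifts are non-positive are resampled (standard
    convention).  Returns (choice, rt, drifts, starts) for provenance.
    """
    drift_means = np.asarray(drift_means, dtype=float)
    n = drift_means.shape[0]
    b = np.broadcast_to(np.asarray(b, dtype=float), (n,))
    A = np.broadcast_to(np.asarray(A, dtype=float), (n,))
    t0 = np.broadcast_to(np.asarray(t0, dtype=float), (n,))
    drifts = rng.normal(drift_means, s)
    bad = (drifts <= 0).all(axis=1)
    while bad.any():
        drifts[bad] = rng.normal(drift_means[bad], s)
        bad = (drifts <= 0).all(axis=1)
    starts = rng.uniform(0.0, 1.0, size=(n, 2)) * A[:, None]
    with np.errstate(divide="ignore"):
        finish = np.where(drifts > 0, (b[:, None] - starts) / drifts, np.inf)
    choice = np.argmin(finish, axis=1).astype(np.int64)
    rt = t0 + finish[np.arange(n), choice]
    return choice, rt, drifts, starts


class _LBAData(NamedTuple):
    rt: np.ndarray
    choice: np.ndarray


class LBAModel(Model):
    """Two-accumulator LBA with drift means (nu, 1 - nu)."""

    name = "lba"
    choice_column = "choice"

    def param_specs(self):
        return (
            ParameterSpec("nu", 0.0, 1.5, grid_points=15),
            ParameterSpec("s", 0.01, 1.0, grid_points=3),
            ParameterSpec("b", 0.5, 3.0, grid_points=3),
            ParameterSpec("A", 0.05, 2.5, grid_points=15),
            ParameterSpec("t0", 0.01, 1.0, grid_points=3),
        )

    def prepare(self, trials):
        return _LBAData(
            np.asarray(trials["rt"], dtype=float),
            np.asarray(trials["choice"], dtype=np.int64),
        )

    def n_trials(self, data):
        return int(data.rt.shape[0])

    def per_trial_loglik(self, data, theta):
        nu, s, b, A, t0 = (float(v) for v in theta)
        if b < A or s <= 0:
            return np.full(data.rt.shape[0], LOG_FLOOR)
        dt = data.rt - t0
        g0 = lba_pdf(dt, nu, s, b, A) * (1.0 - lba_cdf(dt, 1.0 - nu, s, b, A))
        g1 = lba_pdf(dt, 1.0 - nu, s, b, A) * (1.0 - lba_cdf(dt, nu, s, b, A))
        p_none = float(norm.cdf(-nu / s) * norm.cdf(-(1.0 - nu) / s))
        denom = 1.0 - p_none
        if denom < 1e-10:
            return np.full(data.rt.shape[0], LOG_FLOOR)
        g = np.where(data.choice == 0, g0, g1) / denom
        return np.maximum(np.log(np.maximum(g, 1e-300)), LOG_FLOOR)

    def deviance_batch(self, data, thetas, excl=None, excl_n=None):
        thetas = np.ascontiguousarray(np.atleast_2d(thetas), dtype=float)
        P = thetas.shape[0]
        if excl is None:
            excl = np.zeros((P, 1), dtype=np.int64)
            excl_n = np.zeros(P, dtype=np.int64)
        out = np.empty(P)
        lba_deviance_batch(
            data.rt, data.choice, thetas,
            np.ascontiguousarray(excl, dtype=np.int64),
            np.ascontiguousarray(excl_n, dtype=np.int64), out,
        )
        return out

    def simulate(self, trials, theta, rng):
        th = self.theta_matrix(theta, len(trials))
        drift_means = np.column_stack([th[:, 0], 1.0 - th[:, 0]])
        choice, rt, drifts, starts = sample_lba_trials(
            drift_means, float(th[0, 1]), th[:, 2], th[:, 3], th[:, 4], rng
        )
        out = trials.copy()
        out["choice"] = choice
        out["rt"] = rt
        out["drift_0"] = drifts[:, 0]
        out["drift_1"] = drifts[:, 1]
        out["start_0"] = starts[:, 0]
        out["start_1"] = starts[:, 1]
        return out
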
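"""Compiled likelihood kernels.

These are the inner loops behind the leave-one-trial-out batch fits: each
kernel evaluates the total deviance of a stack of parameter vectors, where
problem ``p`` may exclude a set of trials (the left-out unit).  The
formulations mirror the plain-numpy ``per_trial_loglik`` implementations in
the model classes; agreement between the two paths is asserted in the test
suite.

Probability floor: per-trial likelihoods are floored at 1e-300 before the
logarithm so a single impossible observation yields a very bad but finite
deviance instead of propagating ``-inf`` through the simplex.
"""

import math

import numpy as np
from numba import njit

SQRT2 = math.sqrt(2.0)
INV_SQRT_2PI = 1.0 / math.sqrt(2.0 * math.pi)
LOG_FLOOR = math.log(1e-300)


@njit(cache=True)
def _norm_cdf(x):
    return 0.5 * (1.0 + math.erf(x / SQRT2))


@njit(cache=True)
def _norm_pdf(x):
    return INV_SQRT_2PI * math.exp(-0.5 * x * x)


# ---------------------------------------------------------------------------
# Hyperbolic discounting + softmax (choice-only model)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _hd_trial_ll(amounts, delays, choice_t, t, kappa, beta):
    K = amounts.shape[1]
    m = -1.0e308
    for k in range(K):
        u = beta * amounts[t, k] / (1.0 + kappa * delays[t, k])
        if u > m:
            m = u
    s = 0.0
    for k in range(K):
        u = beta * amounts[t, k] / (1.0 + kappa * delays[t, k])
        s += math.exp(u - m)
    uc = beta * amounts[t, choice_t] / (1.0 + kappa * delays[t, choice_t])
    ll = (uc - m) - math.log(s)
    if ll < LOG_FLOOR:
        ll = LOG_FLOOR
    return ll


@njit(cache=True)
def hd_deviance_batch(amounts, delays, choice, thetas, excl, excl_n, out):
    # Kahan-compensated accumulation: leave-one-out works with deviance
    # differences a few ulp above the total, so naive summation noise
    # (~n*eps) would swamp the smallest resolvable parameter shifts.
    P = thetas.shape[0]
    n = choice.shape[0]
    for p in range(P):
        kappa = thetas[p, 0]
        beta = thetas[p, 1]
        tot = 0.0
        comp = 0.0
        for t in range(n):
            y = _hd_trial_ll(amounts, delays, choice[t], t, kappa, beta) - comp
            s = tot + y
            comp = (s - tot) - y
            tot = s
        for j in range(excl_n[p]):
            t = excl[p, j]
            y = -_hd_trial_ll(amounts, delays, choice[t], t, kappa, beta) - comp
            s = tot + y
            comp = (s - tot) - y
            tot = s
        out[p] = -2.0 * tot


# ---------------------------------------------------------------------------
# Linear ballistic accumulator (two accumulators, shared s, b, A, t0)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _lba_cdf(t, v, s, b, A):
    """P(accumulator crosses b by decision time t); defective for v << 0."""
    if t <= 0.0:
        return 0.0
    ts = t * s
    if A < 1e-10:
        return _norm_cdf((v - b / t) / s)
    z1 = (b - A - t * v) / ts
    z2 = (b - t * v) / ts
    F = (
        1.0
        + (b - A - t * v) / A * _norm_cdf(z1)
        - (b - t * v) / A * _norm_cdf(z2)
        + ts / A * _norm_pdf(z1)
        - ts / A * _norm_pdf(z2)
    )
    if F < 0.0:
        F = 0.0
    if F > 1.0:
        F = 1.0
    return F


@njit(cache=True)
def _lba_pdf(t, v, s, b, A):
    if t <= 0.0:
        return 0.0
    ts = t * s
    if A < 1e-10:
        return (b / (t * t)) * _norm_pdf((b / t - v) / s) / s
    z1 = (b - A - t * v) / ts
    z2 = (b - t * v) / ts
    f = (-v * _norm_cdf(z1) + s * _norm_pdf(z1) + v * _norm_cdf(z2) - s * _norm_pdf(z2)) / A
    if f < 0.0:
        f = 0.0
    return f


@njit(cache=True)
def _lba2_trial_ll(rt_t, choice_t, v0, v1, s, b, A, t0):
    dt = rt_t - t0
    if dt <= 0.0 or b < A or s <= 0.0:
        return LOG_FLOOR
    # condition on at least one accumulator having a positive drift
    denom = 1.0 - _norm_cdf(-v0 / s) * _norm_cdf(-v1 / s)
    if denom < 1e-10:
        return LOG_FLOOR
    if choice_t == 0:
        g = _lba_pdf(dt, v0, s, b, A) * (1.0 - _lba_cdf(dt, v1, s, b, A))
    else:
        g = _lba_pdf(dt, v1, s, b, A) * (1.0 - _lba_cdf(dt, v0, s, b, A))
    g /= denom
    if g < 1e-300:
        return LOG_FLOOR
    return math.log(g)


@njit(cache=True)
def hdlba_deviance_batch(x_i, d_i, x_j, d_j, choice, rt, thetas, excl, excl_n, out):
    """theta = (kappa, lambda, s, b, A, t0)."""
    P = thetas.shape[0]
    n = choice.shape[0]
    for p in range(P):
        kappa = thetas[p, 0]
        lam = thetas[p, 1]
        s = thetas[p, 2]
        b = thetas[p, 3]
        A = thetas[p, 4]
        t0 = thetas[p, 5]
        tot = 0.0
        comp = 0.0
        for t in range(n):
            ui = x_i[t] / (1.0 + kappa * d_i[t])
            uj = x_j[t] / (1.0 + kappa * d_j[t])
            v0 = 0.5 + lam * (ui - uj)
            y = _lba2_trial_ll(rt[t], choice[t], v0, 1.0 - v0, s, b, A, t0) - comp
            acc = tot + y
            comp = (acc - tot) - y
            tot = acc
        for j in range(excl_n[p]):
            t = excl[p, j]
            ui = x_i[t] / (1.0 + kappa * d_i[t])
            uj = x_j[t] / (1.0 + kappa * d_j[t])
            v0 = 0.5 + lam * (ui - uj)
            y = -_lba2_trial_ll(rt[t], choice[t], v0, 1.0 - v0, s, b, A, t0) - comp
            acc = tot + y
            comp = (acc - tot) - y
            tot = acc
        out[p] = -2.0 * tot


@njit(cache=True)
def lba_deviance_batch(rt, choice, thetas, excl, excl_n, out):
    """theta = (nu, s, b, A, t0); drift means are (nu, 1 - nu)."""
    P = thetas.shape[0]
    n = choice.shape[0]
    for p in range(P):
        nu = thetas[p, 0]
        s = thetas[p, 1]
        b = thetas[p, 2]
        A = thetas[p, 3]
        t0 = thetas[p, 4]
        tot = 0.0
        comp = 0.0
        for t in range(n):
            y = _lba2_trial_ll(rt[t], choice[t], nu, 1.0 - nu, s, b, A, t0) - comp
            acc = tot + y
            comp = (acc - tot) - y
            tot = acc
        for j in range(excl_n[p]):
            t = excl[p, j]
            y = -_lba2_trial_ll(rt[t], choice[t], nu, 1.0 - nu, s, b, A, t0) - comp
            acc = tot + y
            comp = (acc - tot) - y
            tot = acc
        out[p] = -2.0 * tot
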
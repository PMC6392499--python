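"""Maximum-likelihood estimation: grid search plus constrained simplex.

Estimation everywhere in this package is a two-step procedure: a
deterministic grid search over the free parameters picks start values, and a
bound-constrained Nelder-Mead simplex then minimizes the deviance
(-2 log-likelihood).  The convergence tolerance defaults to 1e-13 — far
stricter than typical optimizer defaults — because leave-one-trial-out has
to resolve deviance differences caused by a single trial, which shrink with
the number of trials.  A lenient tolerance produces visibly quantized
("tied") leave-out estimates on long experiments; see the methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .optimize import nelder_mead_batch

__all__ = [
    "ParameterSpec",
    "FitConfig",
    "ModelFit",
    "EstimationError",
    "DegenerateEstimateError",
    "grid_search",
    "fit",
    "refit_subset",
]


class EstimationError(RuntimeError):
    """Raised when no admissible parameter value could be evaluated."""


class DegenerateEstimateError(ValueError):
    """Raised when a closed-form estimate falls outside the admissible range."""


@dataclass(frozen=True)
class ParameterSpec:
    """Bounds, start-value grid, and fixed-value handling for one parameter.

    ``lower``/``upper`` constrain the simplex.  The grid used to pick start
    values may span a narrower, empirically plausible range
    (``grid_lower``/``grid_upper``): a 25-point grid over a wide formal
    bound like [0, 1] can be far coarser than the scale on which the
    likelihood varies, stranding the simplex in a local minimum.
    """

    name: str
    lower: float
    upper: float
    grid_points: int = 25
    fixed: bool = False
    fixed_value: Optional[float] = None
    grid_lower: Optional[float] = None
    grid_upper: Optional[float] = None

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower bound must be below upper bound")
        if self.grid_points < 1:
            raise ValueError(f"{self.name}: grid_points must be >= 1")
        if self.fixed and self.fixed_value is None:
            raise ValueError(f"{self.name}: fixed parameter needs a fixed_value")

    def with_fixed(self, value: float) -> "ParameterSpec":
        return ParameterSpec(
            self.name, self.lower, self.upper, self.grid_points, True, float(value),
            self.grid_lower, self.grid_upper,
        )

    def grid(self) -> np.ndarray:
        lo = self.lower if self.grid_lower is None else self.grid_lower
        hi = self.upper if self.grid_upper is None else self.grid_upper
        return np.linspace(lo, hi, self.grid_points)


@dataclass(frozen=True)
class FitConfig:
    """Optimizer settings.

    ``tolerance`` applies to both the function-value and the parameter
    spread of the simplex.  ``refit_rel_step`` sets the initial simplex size
    (relative to the start value) for warm-started refits, which begin at
    the all-trial estimates and only need to travel a distance of order
    1/n.  Restart ``r`` of a multi-start fit uses the seed sequence
    ``(rng_seed, r)``.
    """

    tolerance: float = 1e-13
    max_iterations: Optional[int] = None
    n_restarts: int = 0
    rng_seed: int = 0
    rel_step: float = 0.05
    abs_step: float = 0.00025
    refit_rel_step: float = 1e-3
    refit_abs_step: float = 1e-6
    x_tolerance: Optional[float] = None  # None: same as tolerance; inf: converge on deviance spread only

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    @property
    def xatol(self) -> float:
        return self.tolerance if self.x_tolerance is None else self.x_tolerance


@dataclass
class ModelFit:
    """Result of one maximum-likelihood fit."""

    param_names: tuple
    estimates: np.ndarray
    deviance: float
    per_trial_deviance: np.ndarray
    converged: bool
    n_evaluations: int
    start_values: np.ndarray
    degenerate: bool = False

    def estimate(self, name: str) -> float:
        return float(self.estimates[self.param_names.index(name)])

    def to_dict(self) -> dict:
        return {
            "param_names": list(self.param_names),
            "estimates": [float(v) for v in self.estimates],
            "deviance": float(self.deviance),
            "converged": bool(self.converged),
            "n_evaluations": int(self.n_evaluations),
            "start_values": [float(v) for v in self.start_values],
            "degenerate": bool(self.degenerate),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def per_trial_deviance_to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"trial": np.arange(len(self.per_trial_deviance)), "deviance": self.per_trial_deviance}
        ).to_csv(path, index=False)


def _resolve_specs(model, specs):
    specs = tuple(specs) if specs is not None else tuple(model.param_specs())
    names = tuple(s.name for s in specs)
    if names != tuple(model.param_names):
        raise ValueError(f"specs must cover parameters {model.param_names} in order, got {names}")
    return specs


def _free_mask(specs) -> np.ndarray:
    return np.array([not s.fixed for s in specs], dtype=bool)


def _fixed_template(specs) -> np.ndarray:
    return np.array([s.fixed_value if s.fixed else np.nan for s in specs], dtype=float)


def _expand(theta_free, template, free):
    theta = template.copy()
    theta[free] = theta_free
    return theta


def grid_search(model, trials, specs=None, config=None):
    """Deviance-minimizing point of the cartesian parameter grid.

    Fixed parameters are excluded from the grid and held at their fixed
    value.  Deterministic: ties resolve to the lexicographically first grid
    point.  Returns the full parameter vector.
    """
    specs = _resolve_specs(model, specs)
    data = model.prepare(trials) if hasattr(trials, "columns") else trials
    free = _free_mask(specs)
    if not free.any():
        raise ValueError("grid_search needs at least one free parameter")
    template = _fixed_template(specs)
    axes = [s.grid() for s, fr in zip(specs, free) if fr]
    mesh = np.meshgrid(*axes, indexing="ij")
    pts_free = np.column_stack([m.ravel() for m in mesh])
    thetas = np.repeat(template[None, :], pts_free.shape[0], axis=0)
    thetas[:, free] = pts_free
    dev = model.deviance_batch(data, thetas)
    if not np.isfinite(dev).any():
        raise EstimationError("no grid point produced a finite deviance")
    return thetas[int(np.argmin(dev))]


def fit(model, trials, specs=None, config=None, start=None):
    """Fit a model to a trial table by deviance minimization.

    Uses the model's analytic maximum-likelihood estimate when one exists
    (e.g. the binomial success probability); otherwise grid search for start
    values followed by the constrained simplex.  ``start`` (a full parameter
    vector) skips the grid search.  With ``config.n_restarts > 0`` the
    simplex additionally restarts from that many random in-bounds points and
    the best run wins.
    """
    specs = _resolve_specs(model, specs)
    config = config or FitConfig()
    data = model.prepare(trials) if hasattr(trials, "columns") else trials
    free = _free_mask(specs)
    if not free.any():
        raise ValueError("fit needs at least one free parameter")
    if model.n_trials(data) < 1:
        raise ValueError("fit needs a non-empty dataset")
    template = _fixed_template(specs)

    theta_cf = model.closed_form_mle(data, free, template)
    if theta_cf is not None:
        ptd = -2.0 * model.per_trial_loglik(data, theta_cf)
        return ModelFit(
            param_names=tuple(model.param_names),
            estimates=theta_cf,
            deviance=float(ptd.sum()),
            per_trial_deviance=ptd,
            converged=True,
            n_evaluations=1,
            start_values=theta_cf.copy(),
        )

    if start is None:
        start = grid_search(model, data, specs, config)
    else:
        start = np.asarray(start, dtype=float)

    lower = np.array([s.lower for s, fr in zip(specs, free) if fr])
    upper = np.array([s.upper for s, fr in zip(specs, free) if fr])

    starts = [np.asarray(start, dtype=float)[free]]
    for r in range(config.n_restarts):
        rng = np.random.default_rng([config.rng_seed, r])
        starts.append(rng.uniform(lower, upper))

    def objective(idx, X):
        thetas = np.repeat(template[None, :], X.shape[0], axis=0)
        thetas[:, free] = X
        return model.deviance_batch(data, thetas)

    x0 = np.vstack(starts)
    res = nelder_mead_batch(
        objective,
        x0,
        lower,
        upper,
        xatol=config.xatol,
        fatol=config.tolerance,
        max_iter=config.max_iterations,
        rel_step=config.rel_step,
        abs_step=config.abs_step,
    )
    winner = int(np.argmin(res.f))
    theta = _expand(res.x[winner], template, free)
    ptd = -2.0 * model.per_trial_loglik(data, theta)
    return ModelFit(
        param_names=tuple(model.param_names),
        estimates=theta,
        deviance=float(ptd.sum()),
        per_trial_deviance=ptd,
        converged=bool(res.converged[winner]),
        n_evaluations=int(res.n_eval),
        start_values=_expand(x0[winner], template, free),
    )


def refit_subset(model, trials, keep, free, fixed_to: ModelFit, config=None):
    """Re-estimate the named ``free`` parameters on a subset of trials.

    All other parameters are held at their estimates in ``fixed_to`` and the
    optimization starts from those estimates, per the leave-one-out recipe.
    A subset on which a parameter is structurally unidentified (for binary
    choice models: an option never chosen) is flagged degenerate on the
    returned fit rather than raising.
    """
    config = config or FitConfig()
    keep = np.asarray(keep, dtype=bool)
    if keep.sum() < 1:
        raise ValueError("keep-mask must retain at least one trial")
    if not hasattr(trials, "columns"):
        raise TypeError("refit_subset expects a trial table (DataFrame)")
    sub = trials.loc[keep]
    specs = []
    for spec in model.param_specs():
        if spec.name in free:
            specs.append(ParameterSpec(spec.name, spec.lower, spec.upper, spec.grid_points))
        else:
            specs.append(spec.with_fixed(fixed_to.estimate(spec.name)))
    cfg = config
    result = fit(model, sub, specs, cfg, start=fixed_to.estimates)
    data_sub = model.prepare(sub)
    result.degenerate = bool(model.subset_is_degenerate(data_sub))
    return result
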
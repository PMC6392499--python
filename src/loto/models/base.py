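"""Common model interface.

A model couples a likelihood over a trial table with a generative simulator.
Trial tables are pandas DataFrames with model-specific columns (see each
model's docstring for the column dictionary); ``prepare`` converts a table
once into plain arrays so that repeated likelihood evaluations inside the
optimizer touch no pandas machinery.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = ["Model", "Observation", "simulate_observation", "PROB_FLOOR", "LOG_FLOOR"]

PROB_FLOOR = 1e-300
LOG_FLOOR = float(np.log(PROB_FLOOR))


@dataclass(frozen=True)
class Observation:
    """A single simulated outcome: the chosen option and, for response-time
    models, the response time in seconds."""

    choice: int
    rt: Optional[float] = None


class Model(ABC):
    """Abstract cognitive model: likelihood + simulator."""

    name: str = "model"

    @abstractmethod
    def param_specs(self):
        """Default :class:`~loto.fitting.ParameterSpec` tuple."""

    @property
    def param_names(self):
        return tuple(s.name for s in self.param_specs())

    @abstractmethod
    def prepare(self, trials):
        """Convert a trial table into the model's internal array bundle."""

    @abstractmethod
    def per_trial_loglik(self, data, theta) -> np.ndarray:
        """Log-likelihood of every trial at the full parameter vector."""

    @abstractmethod
    def n_trials(self, data) -> int:
        ...

    @abstractmethod
    def simulate(self, trials, theta, rng):
        """Draw observations from the model's generative process.

        ``theta`` is either one parameter vector or an ``(n_trials, k)``
        matrix of trial-wise vectors.  Returns a copy of ``trials`` with the
        observation columns filled in.
        """

    # -- hooks with sensible defaults -------------------------------------

    def deviance_batch(self, data, thetas, excl=None, excl_n=None) -> np.ndarray:
        """Total deviance for a stack of parameter vectors.

        Problem ``p`` excludes the trials listed in ``excl[p, :excl_n[p]]``.
        Models with compiled kernels override this; the fallback loops over
        ``per_trial_loglik``.
        """
        thetas = np.atleast_2d(thetas)
        out = np.empty(thetas.shape[0])
        for p in range(thetas.shape[0]):
            ll = self.per_trial_loglik(data, thetas[p])
            tot = ll.sum()
            if excl is not None and excl_n is not None and excl_n[p] > 0:
                tot -= ll[excl[p, : excl_n[p]]].sum()
            out[p] = -2.0 * tot
        return out

    def closed_form_mle(self, data, free, template, exclude=None):
        """Analytic MLE where one exists (``None`` otherwise)."""
        return None

    def degenerate_unit_mask(self, data, units) -> np.ndarray:
        """Units whose removal leaves a parameter structurally unidentified."""
        return np.zeros(len(units), dtype=bool)

    def subset_is_degenerate(self, data) -> bool:
        return False

    def theta_matrix(self, theta, n) -> np.ndarray:
        """Broadcast a parameter vector to an ``(n, k)`` trial-wise matrix."""
        theta = np.asarray(theta, dtype=float)
        if theta.ndim == 1:
            return np.repeat(theta[None, :], n, axis=0)
        if theta.shape[0] != n:
            raise ValueError(f"trial-wise parameters have {theta.shape[0]} rows, expected {n}")
        return theta


def simulate_observation(model: Model, trial, theta, rng) -> Observation:
    """Simulate a single trial's outcome from ``model``'s generative process."""
    import pandas as pd

    table = trial.to_frame().T if hasattr(trial, "to_frame") else pd.DataFrame([trial])
    table = table.reset_index(drop=True)
    sim = model.simulate(table, np.atleast_2d(np.asarray(theta, dtype=float)), rng)
    rt = float(sim["rt"].iloc[0]) if "rt" in sim.columns and not np.isnan(sim["rt"].iloc[0]) else None
    return Observation(choice=int(sim[model.choice_column].iloc[0]), rt=rt)
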
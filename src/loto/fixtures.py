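"""Deterministic worked-example datasets and reference experiments.

Every fixture is generated in code (nothing is shipped as data) and
regenerates bit-identically from its stored seed, so the full test suite
runs without any download.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .models.binomial import BinomialModel
from .simulate import SimulatedExperiment, TrialwiseVariabilitySpec, simulate_experiment

__all__ = ["make_toy_binomial", "make_example_trials", "make_reference_experiment", "DESK_SCALE", "FULL_SCALE"]

DESK_SCALE = {"n_participants": 8, "n_trials": 80}
FULL_SCALE = {"n_participants": 30, "n_trials": 160}


def make_toy_binomial() -> pd.DataFrame:
    """The classic counting example: 5 successes in 10 trials.

    Trial 0 is a success and trial 1 a failure, so the leave-one-out deltas
    of the first two trials are 1/18 and -1/18 (difference 1/9)."""
    return BinomialModel.from_counts(k=5, n=10)


def make_example_trials() -> pd.DataFrame:
    """Two canonical intertemporal trials, each duplicated with one
    immediate and one delayed choice.

    Trial pair 1: $20 now vs $50 in 20 days (closed-form kappa 0.075);
    trial pair 2: $18 now vs $100 in 25 days (closed-form kappa 0.182).
    """
    return pd.DataFrame(
        {
            "x_i": [20.0, 20.0, 18.0, 18.0],
            "d_i": [0.0, 0.0, 0.0, 0.0],
            "x_j": [50.0, 50.0, 100.0, 100.0],
            "d_j": [20.0, 20.0, 25.0, 25.0],
            "choice": [0, 1, 0, 1],
            "pair": [1, 1, 2, 2],
        }
    )


def make_reference_experiment(model_name: str, scale: str = "desk", seed: int = 0) -> SimulatedExperiment:
    """Seeded experiment under the standard sampling laws.

    ``scale`` is ``"full"`` (30 participants x 160 trials) or ``"desk"``
    (8 x 80, same laws).  Known models: ``hd``, ``hdlba``, ``lba``,
    ``memory``.
    """
    if scale not in ("desk", "full"):
        raise ValueError("scale must be 'desk' or 'full'")
    dims = FULL_SCALE if scale == "full" else DESK_SCALE
    if model_name == "hd":
        variability = {"kappa": TrialwiseVariabilitySpec("kappa", sd=0.01)}
        return simulate_experiment("hd", variability=variability, seed=seed, **dims)
    if model_name == "hdlba":
        variability = {
            "kappa": TrialwiseVariabilitySpec("kappa", sd=0.01),
            "b": TrialwiseVariabilitySpec("b", sd=0.4),
        }
        return simulate_experiment("hdlba", variability=variability, seed=seed, **dims)
    if model_name == "lba":
        return simulate_experiment("lba", seed=seed, **dims)
    if model_name == "memory":
        return _memory_experiment(seed=seed, **dims)
    raise ValueError(f"unknown model {model_name!r}")


def _memory_experiment(n_participants: int, n_trials: int, seed: int) -> SimulatedExperiment:
    """Synthetic remember-and-decide decision phase.

    Six items per block (half encoded once, half twice) with standardized
    subjective values; each item appears in three decision trials; the
    deliberation window alternates between 1 s and 5 s.  Item-level memory
    variability enters as truncated Gaussian jitter on the item's recall
    probability.
    """
    frames, part_rows = [], []
    n_blocks = max(n_trials // 9, 1)
    for p in range(n_participants):
        rng = np.random.default_rng([seed, p])
        sigma = rng.uniform(1.0, 3.0)
        alpha = rng.uniform(0.5, 0.8)
        beta_mem = rng.uniform(0.7, 0.95)
        g = rng.normal(0.0, 0.3)
        rows = []
        for blk in range(n_blocks):
            items = [f"b{blk}i{k}" for k in range(6)]
            enc = {it: 1 if k < 3 else 2 for k, it in enumerate(items)}
            val = {it: rng.normal(0.0, 1.0) for it in items}
            base = {it: alpha if enc[it] == 1 else beta_mem for it in items}
            mem = {}
            for it in items:
                m = rng.normal(base[it], 0.1)
                mem[it] = float(np.clip(m, 0.0, 1.0))
            # each item appears in exactly 3 of the 9 pairings: a complete
            # bipartite design over a random 3/3 split of the items
            perm = [items[i] for i in rng.permutation(6)]
            chosen = [(perm[i], perm[3 + j]) for i in range(3) for j in range(3)]
            chosen = [chosen[i] for i in rng.permutation(9)]
            for k, (a, b) in enumerate(chosen):
                t_delib = 1.0 if k % 2 == 0 else 5.0
                dv = mem[a] * (val[a] - g) - mem[b] * (val[b] - g)
                p_left = norm.cdf(dv * t_delib / sigma)
                rows.append(
                    {
                        "item_l": a,
                        "item_r": b,
                        "V_l": val[a],
                        "V_r": val[b],
                        "enc_l": enc[a],
                        "enc_r": enc[b],
                        "g": g,
                        "t_delib": t_delib,
                        "choice": int(rng.random() >= p_left),
                        "true_M_l": mem[a],
                        "true_M_r": mem[b],
                    }
                )
        df = pd.DataFrame(rows)
        df["participant"] = p
        df["trial"] = np.arange(len(df))
        frames.append(df)
        part_rows.append(
            {"participant": p, "sigma": sigma, "alpha": alpha, "beta_mem": beta_mem, "g": g}
        )
    return SimulatedExperiment(
        trials=pd.concat(frames, ignore_index=True),
        participants=pd.DataFrame(part_rows),
        config={"model": "memory", "n_participants": n_participants, "n_trials": n_trials},
        seed=seed,
    )
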
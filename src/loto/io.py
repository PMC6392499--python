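"""Reading and writing trial tables, parameters, and results.

Column dictionary for trial tables (CSV, one row per trial):

======================  =====================================================
column                  meaning
======================  =====================================================
``x_i, d_i``            amount / delay (days) of the first (immediate) option
``x_j, d_j``            amount / delay of the second (delayed) option
``x_k, d_k``            third option (three-option task only)
``choice``              0-based index of the chosen option (0 = immediate)
``rt``                  response time in seconds (RT models)
``success``             0/1 outcome (binomial model)
``unit_id``             block / unit key for grouped leave-out
``participant``         participant index in multi-subject tables
``V_l, V_r`` etc.       memory-model columns, see ``loto.models.memory``
======================  =====================================================

Model parameters are serialized as JSON name/value objects.
"""

from __future__ import annotations

import json

import pandas as pd

__all__ = ["read_trials", "write_trials", "read_params", "write_params"]


def read_trials(path) -> pd.DataFrame:
    """Load a trial table from CSV."""
    return pd.read_csv(path)


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_params(path) -> dict:
    """Load a parameter name -> value mapping from JSON."""
    with open(path) as fh:
        return json.load(fh)


def write_params(params: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump({k: float(v) for k, v in params.items()}, fh, indent=2)
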
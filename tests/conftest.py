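import numpy as np
import pytest

from loto.fitting import FitConfig, fit
from loto.models import HDModel
from loto.simulate import TrialwiseVariabilitySpec, simulate_experiment


@pytest.fixture(scope="session")
def hd_experiment():
    """One participant, 160 intertemporal trials, trial-wise discount-rate
    variability at the standard level (SD 0.01)."""
    return simulate_experiment(
        "hd",
        n_participants=1,
        n_trials=160,
        variability={"kappa": TrialwiseVariabilitySpec("kappa", sd=0.01)},
        seed=1,
    )


@pytest.fixture(scope="session")
def hd_trials(hd_experiment):
    return hd_experiment.participant_trials(0)


@pytest.fixture(scope="session")
def hd_fit(hd_trials):
    return fit(HDModel(), hd_trials, config=FitConfig())


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: results never depend on test order
    return np.random.default_rng(20260927)
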
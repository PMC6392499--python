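"""The leave-one-trial-out engine and the single-trial-fitting baseline."""

import numpy as np
import pytest

from loto.core import loto, partial_recovery_correlation, single_trial_fit
from loto.fitting import FitConfig, refit_subset
from loto.fixtures import make_toy_binomial
from loto.models import BinomialModel, HDModel


def test_hd_delta_signs_follow_choice(hd_trials, hd_fit):
    """Removing an immediate-choice trial lowers the discount-rate estimate
    (positive delta) and vice versa; ties can only occur where the trial's
    analytic score is below numerical resolution."""
    res = loto(HDModel(), hd_trials, ["kappa"], all_fit=hd_fit)
    good = ~res.degenerate
    ch = hd_trials["choice"].to_numpy()
    d = res.deltas[:, 0]
    assert np.all(d[good & (ch == 0)] >= 0)
    assert np.all(d[good & (ch == 1)] <= 0)
    # the vast majority resolve strictly; exact ties happen only for trials
    # whose leave-out shift is below double-precision deviance resolution
    assert np.mean(d[good] != 0) > 0.9


def test_fit_improvement_nonnegative(hd_trials, hd_fit):
    res = loto(HDModel(), hd_trials, ["kappa"], all_fit=hd_fit)
    assert np.all(res.fit_improvement >= 0)


def test_loto_agrees_with_refit_subset(hd_trials, hd_fit):
    model = HDModel()
    res = loto(model, hd_trials, ["kappa"], all_fit=hd_fit)
    for t in (0, 7, 101):
        keep = np.ones(len(hd_trials), dtype=bool)
        keep[t] = False
        ref = refit_subset(model, hd_trials, keep, ("kappa",), hd_fit)
        assert res.leaveout_estimates[t, 0] == pytest.approx(ref.estimates[0], abs=1e-7)


def test_loto_grouping_forms():
    """Column grouping and explicit index grouping give identical results."""
    trials = make_toy_binomial()
    model = BinomialModel()
    by_col = loto(model, trials, ["theta"], grouping="unit_id")
    groups = {u: [u] for u in range(len(trials))}
    by_dict = loto(model, trials, ["theta"], grouping=groups)
    np.testing.assert_array_equal(by_col.deltas, by_dict.deltas)


def test_loto_flags_degenerate_units():
    import pandas as pd

    # exactly one immediate choice: its leave-out estimate is unidentified
    rng = np.random.default_rng(0)
    n = 40
    trials = pd.DataFrame(
        {
            "x_i": 20.0,
            "d_i": 0.0,
            "x_j": rng.uniform(20.5, 80, n),
            "d_j": rng.choice([7.0, 30.0, 90.0], n),
            "choice": np.r_[0, np.ones(n - 1, dtype=int)],
        }
    )
    res = loto(HDModel(), trials, ["kappa"])
    assert res.degenerate[0]
    assert not res.degenerate[1:].any()
    assert np.isnan(res.deltas[0, 0])


def test_single_trial_fit_hits_bounds_for_choice_only_model(hd_trials, hd_fit):
    """With only a choice observed, the per-trial discount-rate MLE is the
    upper bound after an immediate choice and the lower bound after a
    delayed choice."""
    res = single_trial_fit(HDModel(), hd_trials, ["kappa"], all_fit=hd_fit)
    ch = hd_trials["choice"].to_numpy()
    est = res.estimates[:, 0]
    assert np.all(np.abs(est[ch == 0] - 1.0) < 1e-6)
    assert np.all(np.abs(est[ch == 1] - 0.0) < 1e-6)
    assert res.at_bound.all()


def test_single_trial_fit_one_trial_dataset(hd_trials, hd_fit):
    """On a one-trial dataset the single-trial fit is just a direct fit."""
    from loto.fitting import ParameterSpec, fit

    model = HDModel()
    one = hd_trials.iloc[[3]].reset_index(drop=True)
    res = single_trial_fit(model, one, ["kappa"], all_fit=hd_fit)
    specs = [
        model.param_specs()[0],
        model.param_specs()[1].with_fixed(hd_fit.estimate("beta")),
    ]
    direct = fit(model, one, specs, start=hd_fit.estimates)
    assert res.estimates[0, 0] == pytest.approx(direct.estimates[0], abs=1e-9)


def test_hdlba_single_trial_estimates_can_be_interior():
    """Response times make interior per-trial estimates possible."""
    from loto.fitting import fit
    from loto.models import HDLBAModel
    from loto.simulate import TrialwiseVariabilitySpec, simulate_experiment

    exp = simulate_experiment(
        "hdlba",
        n_participants=1,
        n_trials=60,
        variability={"kappa": TrialwiseVariabilitySpec("kappa", sd=0.01)},
        seed=4,
    )
    trials = exp.participant_trials(0)
    model = HDLBAModel()
    base = exp.participants.iloc[0]
    specs = [
        s if s.name in ("kappa", "lambda_", "s", "b") else s.with_fixed(float(base[s.name]))
        for s in model.param_specs()
    ]
    cfg = FitConfig(tolerance=1e-9)
    all_fit = fit(model, trials, specs, cfg)
    res = single_trial_fit(model, trials, ["kappa"], config=cfg, all_fit=all_fit)
    interior = ~res.at_bound[:, 0]
    assert interior.mean() > 0.2


def test_simulate_observation_single_trial(rng):
    from loto.models import HDLBAModel, simulate_observation

    trial = {"x_i": 20.0, "d_i": 0.0, "x_j": 50.0, "d_j": 30.0}
    theta = np.array([0.02, 0.1, 0.3, 2.5, 1.0, 0.5])
    obs = simulate_observation(HDLBAModel(), trial, theta, rng)
    assert obs.choice in (0, 1)
    assert obs.rt is not None and obs.rt > 0.5

    hd_obs = simulate_observation(HDModel(), {**trial, "choice": 0}, np.array([0.02, 1.0]), rng)
    assert hd_obs.rt is None and hd_obs.choice in (0, 1)


def test_partial_recovery_correlation_identity_and_degenerate(rng):
    true = rng.normal(0, 1, 60)
    obs = rng.integers(0, 2, 60)
    perfect = partial_recovery_correlation(true, true, obs)
    for v in perfect.by_stratum.values():
        assert v == pytest.approx(1.0)
    assert perfect.pooled_slope == pytest.approx(1.0, abs=1e-10)

    const = np.where(obs == 0, 1.0, 0.0)  # constant within stratum
    res = partial_recovery_correlation(true, const, obs)
    assert all(np.isnan(v) for v in res.by_stratum.values())
    assert all(res.flagged.values())


def test_loto_recovers_positive_within_stratum_correlation(hd_experiment, hd_fit):
    trials = hd_experiment.participant_trials(0)
    res = loto(HDModel(), trials, ["kappa"], all_fit=hd_fit)
    rec = partial_recovery_correlation(
        trials["true_kappa"].to_numpy(), res.deltas[:, 0], trials["choice"].to_numpy()
    )
    assert rec.by_stratum[0] > 0
    assert rec.by_stratum[1] > 0
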
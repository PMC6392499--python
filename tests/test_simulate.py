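"""Synthetic-data generators: choice sets, parameter sampling, noise,
pseudo-neural signals, provenance."""

import numpy as np
import pytest

from loto.simulate import (
    NeuralCalibrationDesign,
    NoiseSpec,
    ParticipantDistributions,
    TaskConfig,
    TrialwiseVariabilitySpec,
    _design_replicate,
    _effect_size,
    generate_choiceset,
    generate_three_option_choiceset,
    inject_noise,
    sample_participants,
    sample_trialwise,
    simulate_experiment,
    simulate_neural,
)

DELAYS = {1, 7, 14, 30, 90, 180, 270, 360}


def test_choiceset_respects_grids_and_balance(rng):
    kappa = 0.01
    trials = generate_choiceset(kappa, TaskConfig(), rng)
    assert len(trials) == 160
    assert set(trials["d_j"]).issubset(DELAYS)
    x = trials["x_j"].to_numpy()
    assert x.min() >= 20.5 and x.max() <= 80.0
    assert np.allclose((x - 20.5) % 0.5, 0.0) or np.allclose((x - 20.5) % 0.5, 0.5)
    stage = trials.attrs["relaxations"]
    lo, hi = 0.45 - 0.05 * stage, 0.55 + 0.05 * stage
    frac = np.mean(20.0 > x / (1 + kappa * trials["d_j"].to_numpy()))
    assert lo < frac < hi


def test_choiceset_relaxes_for_extreme_discount_rates():
    """Near the lower truncation bound of the discount rate the delayed
    option dominates almost everywhere, so the balance window must be
    relaxed before a set is accepted — yet generation always terminates."""
    counts = []
    for seed in range(3):
        rng = np.random.default_rng(seed)
        trials = generate_choiceset(0.001, TaskConfig(), rng)
        assert len(trials) == 160
        counts.append(trials.attrs["relaxations"])
    assert all(c > 0 for c in counts)


def test_three_option_choiceset_ordering_and_probability_cap(rng):
    kappa, beta = 0.01, 1.0
    trials = generate_three_option_choiceset(kappa, beta, TaskConfig(), rng)
    x = trials[["x_i", "x_j", "x_k"]].to_numpy()
    d = trials[["d_i", "d_j", "d_k"]].to_numpy()
    assert np.all(np.diff(x, axis=1) >= 0)
    assert np.all(np.diff(d, axis=1) >= 0)
    u = x / (1 + kappa * d)
    from loto.models import softmax_choice_prob

    p = softmax_choice_prob(u, beta)
    assert p.mean(axis=0).max() <= trials.attrs["threshold"] + 1e-12


def test_three_option_zero_beta_accepts_immediately(rng):
    trials = generate_three_option_choiceset(0.02, 0.0, TaskConfig(), rng)
    assert trials.attrs["threshold"] == pytest.approx(0.34)


def test_participant_sampling_respects_truncation(rng):
    draws = sample_participants(5000, ParticipantDistributions.hd(), rng)
    assert draws["kappa"].between(0.001, 0.07).all()
    assert draws["beta"].between(0.01, 10).all()
    # median of the generating log-normal law survives truncation roughly
    assert np.median(draws["kappa"]) == pytest.approx(np.exp(-4.8), rel=0.15)

    lba = sample_participants(2000, ParticipantDistributions.lba(), rng)
    assert (lba["A"] <= lba["b"]).all()

    hdlba = sample_participants(500, ParticipantDistributions.hdlba(), rng)
    assert hdlba["b"].between(2, 3).all()
    assert (hdlba["lambda_"] == 0.1).all() and (hdlba["t0"] == 0.5).all()


def test_trialwise_sampling_levels_and_truncation(rng):
    assert np.all(sample_trialwise(0.02, TrialwiseVariabilitySpec("kappa", sd=0.01, level=0.0), 50, rng) == 0.02)
    draws = sample_trialwise(0.04, TrialwiseVariabilitySpec("kappa", sd=0.01), 20_000, rng)
    assert draws.std() == pytest.approx(0.01, abs=3 * 0.01 / np.sqrt(2 * 20_000) + 2e-4)
    assert (draws >= 0).all()
    b = sample_trialwise(2.5, TrialwiseVariabilitySpec("b", sd=0.4, lower=1.0), 20_000, rng)
    assert (b >= 1.0).all()
    half_level = sample_trialwise(0.04, TrialwiseVariabilitySpec("kappa", sd=0.01, level=0.5), 20_000, rng)
    assert half_level.std() == pytest.approx(0.005, rel=0.05)
    u = sample_trialwise(0.5, TrialwiseVariabilitySpec("kappa", distribution="uniform", range_=0.35), 5000, rng)
    assert u.min() >= 0.5 - 0.175 and u.max() <= 0.5 + 0.175


def test_noise_injection_levels(rng):
    trials = generate_choiceset(0.01, TaskConfig(), rng)
    ident = inject_noise(trials, NoiseSpec("x_j", level=0.0), rng)
    assert (ident.trials["x_j"] == trials["x_j"]).all()

    big = generate_choiceset(0.01, TaskConfig(n_trials=160), rng)
    noised = [inject_noise(big, NoiseSpec("x_j", level=1.0), rng).trials for _ in range(50)]
    diffs = np.concatenate([(n["x_j"] - big["x_j"]).to_numpy() for n in noised])
    assert diffs.std() == pytest.approx(9.0, rel=0.05)

    d = inject_noise(big, NoiseSpec("d_j", level=1.0), rng)
    assert (d.trials["d_j"] > 0).all()
    assert "orig_d_j" in d.trials.columns

    u = inject_noise(big, NoiseSpec("u_j", level=1.0), rng)
    assert u.utility_noise is not None and u.utility_noise.shape == (160, 2)
    assert np.all(u.utility_noise[:, 0] == 0)


def test_utility_noise_magnitude_is_in_kappa_noise_range(rng):
    """The maximal utility noise (SD 6) lies inside the range of utility
    variance that kappa noise at SD 0.01 induces across baseline discount
    rates (the induced variance is strongly baseline-dependent)."""
    u_var = 36.0
    induced = []
    for kap in (0.004, 0.0082, 0.02, 0.05):
        tr = generate_choiceset(kap, TaskConfig(), rng)
        x, d = tr["x_j"].to_numpy(), tr["d_j"].to_numpy()
        ks = np.maximum(rng.normal(kap, 0.01, (500, 160)), 0)
        u = x[None, :] / (1 + ks * d[None, :])
        induced.append(u.var(axis=0).mean())
    assert min(induced) < u_var < max(induced)


def test_neural_signal_is_unbiased_and_noise_free_limit(rng):
    pi = rng.normal(0.02, 0.01, 5000)
    assert np.array_equal(simulate_neural(pi, 0.0, rng), pi)
    F = simulate_neural(pi, 0.05, rng)
    assert abs((F - pi).mean()) < 3 * 0.05 / np.sqrt(5000)


def test_effect_size_decreases_with_neural_noise(rng):
    design = NeuralCalibrationDesign("hd", "kappa", n_participants=10, n_trials=80)
    ds = []
    for sigma in (0.01, 0.05, 0.2, 1.0, 5.0):
        vals = []
        for r in range(8):
            rep_rng = np.random.default_rng([r, int(sigma * 1000)])
            vals.append(_effect_size(_design_replicate(design, rep_rng), sigma, rep_rng))
        ds.append(np.mean(vals))
    assert np.all(np.diff(ds) < 0.15)  # monotone decreasing up to Monte-Carlo noise
    assert ds[0] > 1.5 and ds[-1] < 0.5


def test_experiment_provenance_regenerates_bit_identically():
    import pandas as pd

    exp = simulate_experiment(
        "hd",
        n_participants=2,
        n_trials=40,
        variability={"kappa": TrialwiseVariabilitySpec("kappa", sd=0.01)},
        neural={"kappa": 0.1},
        seed=9,
    )
    again = exp.regenerate()
    pd.testing.assert_frame_equal(exp.trials, again.trials)
    pd.testing.assert_frame_equal(exp.participants, again.participants)
    assert "F_kappa" in exp.trials.columns and "true_kappa" in exp.trials.columns


def test_experiment_save_roundtrip(tmp_path):
    exp = simulate_experiment("hd", n_participants=1, n_trials=20, seed=3)
    exp.save(tmp_path / "exp")
    import json
    import pandas as pd

    trials = pd.read_csv(tmp_path / "exp" / "trials.csv")
    assert len(trials) == 20
    manifest = json.loads((tmp_path / "exp" / "manifest.json").read_text())
    assert manifest["seed"] == 3


def test_input_noise_keeps_analyst_features_clean():
    """The analyst-side trial table keeps the unperturbed features; only
    choice generation sees the noise."""
    exp_clean = simulate_experiment("hd", n_participants=1, n_trials=40, seed=11)
    exp_noisy = simulate_experiment(
        "hd", n_participants=1, n_trials=40, seed=11, input_noise=NoiseSpec("x_j", level=1.0)
    )
    np.testing.assert_array_equal(
        exp_clean.trials["x_j"].to_numpy(), exp_noisy.trials["x_j"].to_numpy()
    )
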
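"""LBA density/CDF pair, defective density, drift-mean mapping, simulator."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from loto.models import (
    HDLBAModel,
    LBAModel,
    LBAParams,
    hdlba_drift_means,
    lba_cdf,
    lba_defective_density,
    lba_pdf,
    sample_lba_trials,
)

PARAMS = LBAParams(nu=0.7, s=0.3, b=2.5, A=1.0, t0=0.5)
DRIFTS = np.array([0.7, 0.3])


def test_density_zero_before_nondecision_time():
    assert lba_defective_density(PARAMS.t0, 0, PARAMS, DRIFTS) == 0.0
    assert lba_defective_density(0.2, 1, PARAMS, DRIFTS) == 0.0


def test_defective_densities_integrate_to_one():
    """Quadrature oracle: total probability over both responses."""
    total = 0.0
    for choice in (0, 1):
        val, _ = quad(
            lambda t: lba_defective_density(t, choice, PARAMS, DRIFTS),
            PARAMS.t0,
            np.inf,
            limit=300,
        )
        total += val
    assert total == pytest.approx(1.0, abs=1e-3)


def test_density_matches_simulation_cdf(rng):
    """Joint (choice, RT) CDF agrees with a large simulation."""
    n = 200_000
    ch, rt, _, _ = sample_lba_trials(np.tile(DRIFTS, (n, 1)), PARAMS.s, PARAMS.b, PARAMS.A, PARAMS.t0, rng)
    for x in (2.0, 3.0, 5.0):
        for c in (0, 1):
            emp = float(((rt <= x) & (ch == c)).mean())
            ana, _ = quad(lambda t: lba_defective_density(t, c, PARAMS, DRIFTS), PARAMS.t0, x, limit=200)
            assert emp == pytest.approx(ana, abs=4e-3)


def test_accuracy_increases_with_drift_mean():
    masses = []
    for nu in np.linspace(0.5, 0.9, 5):
        p = LBAParams(nu, 0.3, 2.5, 1.0, 0.5)
        val, _ = quad(
            lambda t: lba_defective_density(t, 0, p, np.array([nu, 1 - nu])),
            p.t0,
            np.inf,
            limit=300,
        )
        masses.append(val)
    assert np.all(np.diff(masses) > 0)


def test_zero_start_range_limit_is_shifted_wald_like():
    """A -> 0: crossing time is b/drift; CDF is a probit in 1/t."""
    t = 2.0
    v, s, b = 0.8, 0.3, 2.0
    assert lba_cdf(t, v, s, b, 1e-14) == pytest.approx(norm.cdf((v - b / t) / s), abs=1e-9)
    h = 1e-6
    fd = (lba_cdf(t + h, v, s, b, 1e-14) - lba_cdf(t - h, v, s, b, 1e-14)) / (2 * h)
    assert lba_pdf(t, v, s, b, 1e-14) == pytest.approx(fd, rel=1e-5)


def test_pdf_is_derivative_of_cdf():
    for v in (0.2, 0.7, 1.4):
        for t in (0.8, 2.0, 4.0):
            if lba_pdf(t, v, 0.3, 2.5, 1.0) < 1e-6:
                continue  # finite differences drown in roundoff for microscopic densities
            h = 1e-6
            fd = (lba_cdf(t + h, v, 0.3, 2.5, 1.0) - lba_cdf(t - h, v, 0.3, 2.5, 1.0)) / (2 * h)
            assert lba_pdf(t, v, 0.3, 2.5, 1.0) == pytest.approx(fd, rel=1e-5, abs=1e-12)


def test_drift_means_sum_to_one(rng):
    assert hdlba_drift_means(5.0, 5.0, 0.1) == (0.5, 0.5)
    v_i, v_j = hdlba_drift_means(12.0, 10.0, 0.1)
    assert (v_i, v_j) == (pytest.approx(0.7), pytest.approx(0.3))
    u = rng.uniform(0, 60, (100, 2))
    vi, vj = hdlba_drift_means(u[:, 0], u[:, 1], 0.1)
    np.testing.assert_allclose(vi + vj, 1.0)


def test_simulated_rts_exceed_nondecision_time(rng):
    import pandas as pd

    trials = pd.DataFrame({"x_i": [20.0] * 160, "d_i": 0.0, "x_j": 50.0, "d_j": 30.0})
    theta = np.array([0.02, 0.1, 0.3, 2.5, 1.0, 0.5])
    sim = HDLBAModel().simulate(trials, theta, rng)
    assert (sim["rt"] > 0.5).all()
    assert set(sim["choice"].unique()) <= {0, 1}


def test_study_settings_produce_realistic_accuracy_and_rt():
    """Under the standard generative settings most participants land in the
    53-89% accuracy and 1.5-2.1 s mean-RT windows."""
    from loto.simulate import ParticipantDistributions, sample_participants

    rng = np.random.default_rng(5)
    ok_acc = ok_rt = 0
    n_participants = 12
    for _ in range(n_participants):
        p = sample_participants(1, ParticipantDistributions.lba(), rng).iloc[0]
        drift_means = np.tile([p["nu"], 1 - p["nu"]], (200, 1))
        ch, rt, _, _ = sample_lba_trials(drift_means, p["s"], p["b"], p["A"], p["t0"], rng)
        acc = (ch == 0).mean()
        ok_acc += 0.53 <= acc <= 0.89
        ok_rt += 1.5 <= rt.mean() <= 2.1
    assert ok_acc >= 0.75 * n_participants
    assert ok_rt >= 0.75 * n_participants


def test_hdlba_kernel_agrees_with_numpy(rng):
    import pandas as pd

    model = HDLBAModel()
    trials = pd.DataFrame(
        {
            "x_i": 20.0,
            "d_i": 0.0,
            "x_j": rng.uniform(20.5, 80, 80),
            "d_j": rng.choice([1, 7, 14, 30, 90, 180, 270, 360], 80).astype(float),
        }
    )
    theta = np.array([0.01, 0.1, 0.3, 2.5, 1.0, 0.5])
    sim = model.simulate(trials, theta, rng)
    data = model.prepare(sim)
    thetas = np.column_stack(
        [
            rng.uniform(0, 0.05, 15),
            np.full(15, 0.1),
            rng.uniform(0.1, 0.6, 15),
            rng.uniform(1.5, 3.5, 15),
            np.full(15, 1.0),
            np.full(15, 0.5),
        ]
    )
    dev_kernel = model.deviance_batch(data, thetas)
    per_trial = [model.per_trial_loglik(data, th) for th in thetas]
    dev_numpy = np.array([-2.0 * ll.sum() for ll in per_trial])
    # compare rows whose likelihood is numerically healthy: deep in the
    # tails the survival term 1 - F amplifies the last-ulp differences
    # between libm's erf (kernel) and scipy's ndtr (reference)
    ok = np.array([ll.min() > -15 for ll in per_trial])
    assert ok.sum() >= 4
    np.testing.assert_allclose(dev_kernel[ok], dev_numpy[ok], rtol=1e-6)


def test_lba_model_loglik_finite_on_simulated_data(rng):
    import pandas as pd

    model = LBAModel()
    trials = pd.DataFrame(index=range(160))
    theta = np.array([0.6, 0.2, 1.5, 1.0, 0.2])
    sim = model.simulate(trials, theta, rng)
    ll = model.per_trial_loglik(model.prepare(sim), theta)
    assert np.isfinite(ll).all()


def test_true_parameters_beat_perturbed_on_average(rng):
    """Simulation oracle: the generating kappa outscores kappa +/- 50%."""
    import pandas as pd

    model = HDLBAModel()
    trials = pd.DataFrame(
        {
            "x_i": 20.0,
            "d_i": 0.0,
            "x_j": rng.uniform(20.5, 80, 160),
            "d_j": rng.choice([1.0, 7, 14, 30, 90, 180, 270, 360], 160),
        }
    )
    theta = np.array([0.02, 0.1, 0.3, 2.5, 1.0, 0.5])
    wins = 0
    n_rep = 40
    for _ in range(n_rep):
        sim = model.simulate(trials, theta, rng)
        data = model.prepare(sim)
        ll_true = model.per_trial_loglik(data, theta).sum()
        up, dn = theta.copy(), theta.copy()
        up[0] *= 1.5
        dn[0] *= 0.5
        wins += ll_true > max(
            model.per_trial_loglik(data, up).sum(), model.per_trial_loglik(data, dn).sum()
        )
    assert wins >= 0.9 * n_rep
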
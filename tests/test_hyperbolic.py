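"""Hyperbolic discounting model: utilities, softmax, score, closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from loto.fitting import DegenerateEstimateError, ParameterSpec, fit
from loto.fixtures import make_example_trials
from loto.models import (
    HDModel,
    HDParams,
    IntertemporalTrial,
    hd_kappa_closed_form,
    hd_loglik,
    hd_score_kappa,
    hd_utility,
    softmax_choice_prob,
)

TRIAL_1 = IntertemporalTrial(x_i=20, x_j=50, d_j=20)
TRIAL_2 = IntertemporalTrial(x_i=18, x_j=100, d_j=25)


def test_utility_discounts_hyperbolically():
    assert hd_utility(20, 0, 0.5) == 20  # immediate option keeps face value
    assert hd_utility(50, 20, 0.075) == pytest.approx(20.0)
    assert hd_utility(100, 25, 82 / 450) == pytest.approx(18.0)  # exact closed-form kappa


def test_softmax_examples():
    np.testing.assert_allclose(softmax_choice_prob([20, 20], 2.0), [0.5, 0.5])
    np.testing.assert_allclose(softmax_choice_prob([3.0, 17.0], 0.0), [0.5, 0.5])
    np.testing.assert_allclose(
        softmax_choice_prob([1.0, 2.0, 3.0], 1.0), [0.0900, 0.2447, 0.6652], atol=5e-5
    )


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    u=st.lists(st.floats(-350, 350), min_size=2, max_size=4),
    beta=st.floats(0, 2),
)
def test_softmax_normalizes_and_stays_finite(u, beta):
    p = softmax_choice_prob(np.array(u), beta)
    assert np.isfinite(p).all()
    assert abs(p.sum() - 1.0) < 1e-12
    assert (p >= 0).all()


def test_loglik_special_cases():
    trials = make_example_trials()
    # beta = 0: every choice has probability 1/2
    assert hd_loglik(trials, HDParams(0.05, 0.0)) == pytest.approx(4 * np.log(0.5))


def test_closed_form_kappa_is_loglik_maximizer():
    """10,000-point grid oracle over kappa for a duplicated trial pair."""
    trials = make_example_trials()
    model = HDModel()
    beta = 2.0
    for pair, expected in ((1, 0.075), (2, 82 / 450)):
        sub = trials[trials["pair"] == pair]
        data = model.prepare(sub)
        grid = np.linspace(0, 1, 10_000)
        lls = [model.per_trial_loglik(data, np.array([k, beta])).sum() for k in grid]
        k_grid = grid[int(np.argmax(lls))]
        assert k_grid == pytest.approx(expected, abs=2e-4)


@pytest.mark.parametrize(
    "trial, expected",
    [(TRIAL_1, 0.075), (TRIAL_2, 82 / 450)],
)
def test_closed_form_kappa_examples(trial, expected):
    for beta in (0.5, 2.0, 5.0):  # equal counts: beta drops out
        assert hd_kappa_closed_form(trial, 1, 1, beta) == pytest.approx(expected, abs=1e-12)
    assert hd_kappa_closed_form(trial, 3, 3, 1.0) == pytest.approx(expected, abs=1e-12)


def test_closed_form_kappa_orders_example_trials():
    assert hd_kappa_closed_form(TRIAL_2, 1, 1, 2.0) > hd_kappa_closed_form(TRIAL_1, 1, 1, 2.0)


def test_closed_form_kappa_vanishing_premium():
    t = IntertemporalTrial(x_i=20, x_j=20.0001, d_j=30)
    assert hd_kappa_closed_form(t, 1, 1, 1.0) == pytest.approx(0.0, abs=1e-5)


def test_closed_form_kappa_requires_both_options_chosen():
    with pytest.raises(DegenerateEstimateError):
        hd_kappa_closed_form(TRIAL_1, 0, 2, 1.0)


def test_closed_form_kappa_is_root_of_summed_score():
    """The analytic estimate zeroes the total score of the repeated trial."""
    for trial in (TRIAL_1, TRIAL_2):
        for n_i, n_j in ((1, 1), (3, 2), (2, 5)):
            beta = 1.3
            k = hd_kappa_closed_form(trial, n_i, n_j, beta)
            params = HDParams(min(k, 1.0), beta)
            score = n_i * hd_score_kappa(trial, 0, params) + n_j * hd_score_kappa(trial, 1, params)
            assert abs(score) < 1e-8


def test_score_sign_follows_choice(rng):
    for _ in range(200):
        trial = IntertemporalTrial(
            x_i=rng.uniform(5, 50),
            x_j=rng.uniform(51, 150),
            d_j=rng.uniform(1, 360),
        )
        params = HDParams(rng.uniform(0, 0.9), rng.uniform(0.05, 4))
        assert hd_score_kappa(trial, 0, params) > 0
        assert hd_score_kappa(trial, 1, params) < 0


def test_score_matches_finite_differences(rng):
    """Analytic derivative vs central finite differences, 1,000 draws."""
    h = 3e-6  # small enough for the steep long-delay trials, large enough for roundoff
    for _ in range(1000):
        kappa = rng.uniform(0.01, 0.9)
        beta = rng.uniform(0.05, 3)
        trial = IntertemporalTrial(
            x_i=rng.uniform(5, 50), x_j=rng.uniform(51, 120), d_j=rng.uniform(1, 360)
        )
        choice = int(rng.integers(2))

        def ll(k):
            # independent oracle: the exact two-option logistic form, whose
            # absolute error scales with |ll| itself (logsumexp would leave
            # O(eps * logits) noise that swamps tiny scores)
            du = trial.x_i - trial.x_j / (1.0 + k * trial.d_j)
            sign = 1.0 if choice == 0 else -1.0
            return -np.logaddexp(0.0, -sign * beta * du)

        # five-point stencil: O(h^4) truncation keeps the comparison at the
        # 1e-6 relative level without running into roundoff
        fd = (ll(kappa - 2 * h) - 8 * ll(kappa - h) + 8 * ll(kappa + h) - ll(kappa + 2 * h)) / (12 * h)
        ana = hd_score_kappa(trial, choice, HDParams(kappa, beta))
        assert ana == pytest.approx(fd, rel=1e-6, abs=1e-12)


def test_fit_on_duplicated_pairs_matches_grid_oracle():
    """Joint MLE over both duplicated example pairs, beta fixed."""
    trials = make_example_trials()
    model = HDModel()
    specs = [
        ParameterSpec("kappa", 0.0, 1.0, 25, grid_upper=0.3),
        ParameterSpec("beta", 0.0, 10.0, fixed=True, fixed_value=2.0),
    ]
    res = fit(model, trials, specs)
    data = model.prepare(trials)
    grid = np.linspace(0, 0.5, 10_000)
    lls = [model.per_trial_loglik(data, np.array([k, 2.0])).sum() for k in grid]
    k_oracle = grid[int(np.argmax(lls))]
    assert res.estimates[0] == pytest.approx(k_oracle, abs=1e-4)


def test_kernel_agrees_with_numpy_loglik(hd_trials):
    model = HDModel()
    data = model.prepare(hd_trials)
    rng = np.random.default_rng(0)
    thetas = np.column_stack([rng.uniform(0, 0.3, 20), rng.uniform(0.01, 5, 20)])
    dev_kernel = model.deviance_batch(data, thetas)
    dev_numpy = np.array(
        [-2.0 * model.per_trial_loglik(data, th).sum() for th in thetas]
    )
    np.testing.assert_allclose(dev_kernel, dev_numpy, rtol=1e-12, atol=1e-9)


def test_simulated_choice_rate_neutral_at_zero_beta(rng):
    import pandas as pd

    trials = pd.DataFrame(
        {"x_i": [20.0] * 10_000, "d_i": 0.0, "x_j": 60.0, "d_j": 90.0, "choice": 0}
    )
    sim = HDModel().simulate(trials, np.array([0.02, 0.0]), rng)
    rate = (sim["choice"] == 0).mean()
    assert abs(rate - 0.5) < 3 * 0.005
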
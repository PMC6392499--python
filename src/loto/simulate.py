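"""Synthetic experiment generation.

Everything the validation pipeline consumes is generated here: adaptive
intertemporal choice sets, participant parameters drawn from truncated
log-normal/uniform laws, trial-wise parameter variability, Gaussian noise in
task inputs or computed utilities, and pseudo-neural signals calibrated to a
target effect size.

Reproducibility: a master seed spawns independent per-participant and
per-replicate streams through ``numpy``'s seed-sequence mechanism — stream
``(seed, p)`` for participant ``p``, ``(seed, rep, p)`` inside replicated
designs — so any experiment regenerates bit-identically from its stored
seed and configuration, and participants can be simulated in any order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import json
import numpy as np
import pandas as pd

from .models.hyperbolic import HDModel, softmax_choice_prob
from .models.hdlba import HDLBAModel
from .models.lba import LBAModel

__all__ = [
    "TaskConfig",
    "ParticipantDistributions",
    "TrialwiseVariabilitySpec",
    "NoiseSpec",
    "NoiseInjection",
    "SimulatedExperiment",
    "generate_choiceset",
    "generate_three_option_choiceset",
    "sample_participants",
    "sample_trialwise",
    "inject_noise",
    "simulate_neural",
    "calibrate_neural_noise",
    "CalibrationResult",
    "NeuralCalibrationDesign",
    "simulate_experiment",
]


@dataclass(frozen=True)
class TaskConfig:
    """Intertemporal choice task layout.

    The immediate option is fixed (x_i at delay 0); delayed amounts come
    from a 0.5-step grid on [20.5, 80] and delays from a fixed set of days.
    A candidate choice set is accepted when the immediate option has the
    higher utility in 45-55% of trials under the participant's baseline
    discount rate; after 1,000 failed attempts the window is widened by 10%
    (5 points per side) and the search repeats.  Three-option sets instead
    require the highest mean softmax choice probability to stay below 0.34,
    relaxed by 0.001 per candidate set.
    """

    n_trials: int = 160
    n_options: int = 2
    x_i: float = 20.0
    d_i: float = 0.0
    delay_set: tuple = (1, 7, 14, 30, 90, 180, 270, 360)
    xj_min: float = 20.5
    xj_max: float = 80.0
    xj_step: float = 0.5
    accept_lo: float = 0.45
    accept_hi: float = 0.55
    relax_step: float = 0.05  # widening per side per stage (10% total)
    attempts_per_stage: int = 1000
    three_option_threshold: float = 0.34
    three_option_relax: float = 0.001


def _amount_grid(config: TaskConfig) -> np.ndarray:
    n = int(round((config.xj_max - config.xj_min) / config.xj_step)) + 1
    return config.xj_min + config.xj_step * np.arange(n)


def generate_choiceset(kappa_baseline: float, config: TaskConfig = TaskConfig(), rng=None) -> pd.DataFrame:
    """Adaptive two-option choice set for a given baseline discount rate.

    Returns a trial table whose fraction of trials with u_i > u_j lies
    inside the (possibly relaxed) acceptance window; the number of
    relaxation stages used is recorded in ``df.attrs["relaxations"]``.
    """
    rng = rng or np.random.default_rng()
    grid = _amount_grid(config)
    delays = np.asarray(config.delay_set, dtype=float)
    stage = 0
    while True:
        lo = config.accept_lo - stage * config.relax_step
        hi = config.accept_hi + stage * config.relax_step
        # attempts drawn in growing chunks; the first acceptable set wins
        remaining = config.attempts_per_stage
        chunk = 32
        while remaining > 0:
            m = min(chunk, remaining)
            d_j = rng.choice(delays, (m, config.n_trials))
            x_j = rng.choice(grid, (m, config.n_trials))
            frac = np.mean(config.x_i > x_j / (1.0 + kappa_baseline * d_j), axis=1)
            hits = np.flatnonzero((frac > lo) & (frac < hi))
            if hits.size:
                a = int(hits[0])
                df = pd.DataFrame(
                    {
                        "x_i": config.x_i,
                        "d_i": config.d_i,
                        "x_j": x_j[a],
                        "d_j": d_j[a],
                    }
                )
                df.attrs["relaxations"] = stage
                return df
            remaining -= m
            chunk *= 4
        stage += 1


def generate_three_option_choiceset(
    kappa: float, beta: float, config: TaskConfig = TaskConfig(), rng=None
) -> pd.DataFrame:
    """Three-option task: amounts and delays sorted so that one option is
    smallest in both, one largest in both; the whole set is resampled (with
    the probability criterion relaxed by 0.001 each round) until no option's
    mean softmax probability exceeds the threshold."""
    rng = rng or np.random.default_rng()
    grid = _amount_grid(config)
    delays = np.asarray(config.delay_set, dtype=float)
    threshold = config.three_option_threshold
    while True:
        x = np.sort(rng.choice(grid, size=(config.n_trials, 3)), axis=1)
        d = np.sort(rng.choice(delays, size=(config.n_trials, 3)), axis=1)
        u = x / (1.0 + kappa * d)
        p = softmax_choice_prob(u, beta)
        if float(p.mean(axis=0).max()) <= threshold:
            df = pd.DataFrame(
                {
                    "x_i": x[:, 0],
                    "d_i": d[:, 0],
                    "x_j": x[:, 1],
                    "d_j": d[:, 1],
                    "x_k": x[:, 2],
                    "d_k": d[:, 2],
                }
            )
            df.attrs["threshold"] = threshold
            return df
        threshold += config.three_option_relax


# ---------------------------------------------------------------------------
# participant- and trial-level parameter sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParticipantDistributions:
    """Per-parameter sampling laws.

    ``laws`` maps a parameter name to one of
    ``("lognormal", mu, sigma, lo, hi)`` (truncated by rejection),
    ``("uniform", lo, hi)``, ``("normal", mu, sd)``, or ``("fixed", value)``.
    """

    laws: dict

    @classmethod
    def hd(cls) -> "ParticipantDistributions":
        return cls(
            {
                "kappa": ("lognormal", -4.8, 1.0, 0.001, 0.07),
                "beta": ("lognormal", -0.77, 0.71, 0.01, 10.0),
            }
        )

    @classmethod
    def hdlba(cls) -> "ParticipantDistributions":
        return cls(
            {
                "kappa": ("lognormal", -4.8, 1.0, 0.001, 0.07),
                "lambda_": ("fixed", 0.1),
                "s": ("fixed", 0.3),
                "b": ("uniform", 2.0, 3.0),
                "A": ("fixed", 1.0),
                "t0": ("fixed", 0.5),
            }
        )

    @classmethod
    def lba(cls) -> "ParticipantDistributions":
        return cls(
            {
                "nu": ("normal", 0.6, 0.02),
                "s": ("normal", 0.2, 0.02),
                "b": ("fixed", 1.5),
                "A": ("normal", 1.0, 0.1),
                "t0": ("fixed", 0.2),
            }
        )


def _draw(law, rng, constraint=None):
    kind = law[0]
    while True:
        if kind == "lognormal":
            _, mu, sigma, lo, hi = law
            v = rng.lognormal(mu, sigma)
            if not lo <= v <= hi:
                continue
        elif kind == "uniform":
            v = rng.uniform(law[1], law[2])
        elif kind == "normal":
            v = rng.normal(law[1], law[2])
        elif kind == "fixed":
            v = law[1]
        else:
            raise ValueError(f"unknown law {kind!r}")
        if constraint is None or constraint(v):
            return float(v)


def sample_participants(n: int, distributions: ParticipantDistributions, rng=None) -> pd.DataFrame:
    """Draw ``n`` participants' baseline parameters (rejection sampling for
    truncation; the LBA start-point height respects A <= b)."""
    rng = rng or np.random.default_rng()
    rows = []
    for _ in range(n):
        row = {}
        for name, law in distributions.laws.items():
            if name == "A" and "b" in row:
                row[name] = _draw(law, rng, constraint=lambda v, b=row["b"]: v <= b)
            else:
                row[name] = _draw(law, rng)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrialwiseVariabilitySpec:
    """Trial-to-trial variability of one parameter.

    Normal: sd scaled by ``level`` (the 10%..100% grid of the
    misattribution analyses), truncated below at ``lower`` (and above at
    ``upper`` if given).  Uniform: total range ``range_`` scaled by
    ``level``, centred on the baseline.
    """

    parameter: str
    distribution: str = "normal"
    sd: float = 0.0
    range_: float = 0.0
    level: float = 1.0
    lower: float = 0.0
    upper: Optional[float] = None

    def sample(self, baseline: float, n_trials: int, rng) -> np.ndarray:
        return sample_trialwise(baseline, self, n_trials, rng)


def sample_trialwise(baseline: float, spec: TrialwiseVariabilitySpec, n_trials: int, rng) -> np.ndarray:
    """Per-trial parameter values around a participant baseline."""
    if spec.level == 0:
        return np.full(n_trials, baseline)
    if spec.distribution == "normal":
        sd = spec.sd * spec.level
        out = rng.normal(baseline, sd, n_trials)
        bad = out < spec.lower
        if spec.upper is not None:
            bad |= out > spec.upper
        while bad.any():
            out[bad] = rng.normal(baseline, sd, int(bad.sum()))
            bad = out < spec.lower
            if spec.upper is not None:
                bad |= out > spec.upper
        return out
    if spec.distribution == "uniform":
        half = 0.5 * spec.range_ * spec.level
        lo = max(baseline - half, spec.lower)
        hi = baseline + half if spec.upper is None else min(baseline + half, spec.upper)
        return rng.uniform(lo, hi, n_trials)
    raise ValueError(f"unknown distribution {spec.distribution!r}")


# ---------------------------------------------------------------------------
# input/output noise
# ---------------------------------------------------------------------------

_MAX_SD = {"x_j": 9.0, "d_j": 10.0, "u_j": 6.0, "sigma": 2.2}


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian perturbation of a task input (amount, delay), the
    computed utility of the delayed option, or a model parameter; ``level``
    scales the calibrated maximum SD."""

    target: str
    level: float = 1.0
    max_sd: Optional[float] = None

    @property
    def sd(self) -> float:
        base = self.max_sd if self.max_sd is not None else _MAX_SD[self.target]
        return base * self.level


@dataclass
class NoiseInjection:
    """Perturbed copy of a trial table plus provenance.

    ``trials`` carries the perturbed generation-side features (original
    columns preserved as ``orig_<name>``); ``utility_noise`` is the additive
    utility perturbation for targets that do not live in the table.
    """

    trials: pd.DataFrame
    spec: NoiseSpec
    utility_noise: Optional[np.ndarray] = None


def inject_noise(trials: pd.DataFrame, spec: NoiseSpec, rng) -> NoiseInjection:
    """Apply additive Gaussian noise to the named quantity.

    Perturbed delays are clamped to stay positive (a negative delay is
    meaningless); utilities are perturbed via a noise array handed to the
    simulator rather than by rewriting the table.
    """
    out = trials.copy()
    if spec.level == 0:
        return NoiseInjection(out, spec)
    if spec.target in ("x_j", "d_j"):
        out[f"orig_{spec.target}"] = trials[spec.target]
        vals = trials[spec.target].to_numpy(dtype=float) + rng.normal(0.0, spec.sd, len(trials))
        if spec.target == "d_j":
            vals = np.maximum(vals, 1e-6)
        out[spec.target] = vals
        return NoiseInjection(out, spec)
    if spec.target == "u_j":
        noise = np.zeros((len(trials), 2))
        noise[:, 1] = rng.normal(0.0, spec.sd, len(trials))
        return NoiseInjection(out, spec, utility_noise=noise)
    raise ValueError(f"noise target {spec.target!r} not applicable to a trial table")


# ---------------------------------------------------------------------------
# pseudo-neural signals
# ---------------------------------------------------------------------------


def simulate_neural(pi_t, sigma_F: float, rng) -> np.ndarray:
    """Trial-wise neural signal F(pi)_t ~ Normal(pi_t, sigma_F)."""
    pi_t = np.asarray(pi_t, dtype=float)
    if sigma_F < 0:
        raise ValueError("sigma_F must be >= 0")
    return rng.normal(pi_t, sigma_F) if sigma_F > 0 else pi_t.copy()


@dataclass(frozen=True)
class NeuralCalibrationDesign:
    """Design of the effect-size calibration: which model generates the
    behavior, which trial-wise parameter the signal tracks, and which
    observations enter the per-participant regressions as covariates."""

    model: str = "hd"
    parameter: str = "kappa"
    n_participants: int = 30
    n_trials: int = 160
    task: TaskConfig = field(default_factory=TaskConfig)


@dataclass
class CalibrationResult:
    sigma_F: float
    d_mean: float
    d_ci: tuple
    n_reps: int
    history: list


def _standardize(v):
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _design_replicate(design: NeuralCalibrationDesign, rng):
    """Simulate one experiment: per participant the true trial-wise target
    values and the observation covariates (choice, and RT when modeled)."""
    out = []
    for p in range(design.n_participants):
        if design.model == "hd":
            parts = sample_participants(1, ParticipantDistributions.hd(), rng).iloc[0]
            task = TaskConfig(n_trials=design.n_trials)
            trials = generate_choiceset(parts["kappa"], task, rng)
            kt = sample_trialwise(
                parts["kappa"], TrialwiseVariabilitySpec("kappa", sd=0.01), design.n_trials, rng
            )
            theta = np.column_stack([kt, np.full(design.n_trials, parts["beta"])])
            sim = HDModel().simulate(trials, theta, rng)
            pi = kt if design.parameter == "kappa" else np.full(design.n_trials, parts["beta"])
            cov = sim["choice"].to_numpy(dtype=float)[:, None]
        elif design.model == "hdlba":
            parts = sample_participants(1, ParticipantDistributions.hdlba(), rng).iloc[0]
            task = TaskConfig(n_trials=design.n_trials)
            trials = generate_choiceset(parts["kappa"], task, rng)
            kt = sample_trialwise(
                parts["kappa"], TrialwiseVariabilitySpec("kappa", sd=0.01), design.n_trials, rng
            )
            bt = sample_trialwise(
                parts["b"], TrialwiseVariabilitySpec("b", sd=0.4, lower=parts["A"]),
                design.n_trials, rng,
            )
            theta = np.column_stack(
                [
                    kt,
                    np.full(design.n_trials, parts["lambda_"]),
                    np.full(design.n_trials, parts["s"]),
                    bt,
                    np.full(design.n_trials, parts["A"]),
                    np.full(design.n_trials, parts["t0"]),
                ]
            )
            sim = HDLBAModel().simulate(trials, theta, rng)
            pi = kt if design.parameter == "kappa" else bt
            cov = np.column_stack([sim["choice"].to_numpy(dtype=float), sim["rt"].to_numpy(dtype=float)])
        else:
            raise ValueError(f"unknown calibration model {design.model!r}")
        out.append((pi, cov))
    return out


def _effect_size(replicate, sigma_F, rng):
    """Group Cohen's d of the true-parameter regressor at one noise level."""
    coefs = []
    for pi, cov in replicate:
        F = simulate_neural(pi, sigma_F, rng)
        X = np.column_stack(
            [np.ones(len(pi)), _standardize(pi)] + [_standardize(cov[:, c]) for c in range(cov.shape[1])]
        )
        beta, *_ = np.linalg.lstsq(X, F, rcond=None)
        coefs.append(beta[1])
    coefs = np.asarray(coefs)
    return coefs.mean() / coefs.std(ddof=1)


def calibrate_neural_noise(
    design: NeuralCalibrationDesign,
    target_d: float = 1.0,
    n_reps: int = 1000,
    rng=None,
    bracket=(1e-4, 64.0),
    max_bisect: int = 40,
) -> CalibrationResult:
    """Find the noise SD at which the true-parameter regressor reaches the
    target group effect size.

    For a candidate sigma_F, each of ``n_reps`` replicate experiments yields
    one group-level Cohen's d (mean over participants of the standardized
    true-parameter coefficient divided by its across-participant SD); the
    candidate is accepted once the 95% confidence interval of the mean d
    overlaps the target.  The mean d is monotone decreasing in sigma_F, so
    the search is a bracketing bisection (coarse replicate counts while
    bracketing, the full count for the final check).
    """
    rng = rng or np.random.default_rng()
    if target_d <= 0:
        raise ValueError("target_d must be positive")

    def mean_d(sigma, reps, seed_tag):
        ds = np.empty(reps)
        for r in range(reps):
            rep_rng = np.random.default_rng([seed_tag, r, int(rng.integers(2**31))])
            replicate = _design_replicate(design, rep_rng)
            ds[r] = _effect_size(replicate, sigma, rep_rng)
        half = 1.96 * ds.std(ddof=1) / np.sqrt(reps)
        return float(ds.mean()), float(half), ds

    history = []
    coarse = max(n_reps // 10, 20)
    lo, hi = bracket
    d_lo, _, _ = mean_d(lo, coarse, 0)
    d_hi, _, _ = mean_d(hi, coarse, 1)
    if not (d_hi < target_d < d_lo):
        raise ValueError(
            f"bracket {bracket} does not enclose target d={target_d}: d({lo})={d_lo:.3f}, d({hi})={d_hi:.3f}"
        )
    history += [(lo, d_lo), (hi, d_hi)]
    for it in range(max_bisect):
        mid = np.sqrt(lo * hi)  # sigma spans orders of magnitude: bisect in log space
        d_mid, half, _ = mean_d(mid, coarse, 2 + it)
        history.append((mid, d_mid))
        if abs(d_mid - target_d) <= half or (hi / lo) < 1.05:
            d_final, half_final, _ = mean_d(mid, n_reps, 1000 + it)
            history.append((mid, d_final))
            return CalibrationResult(
                sigma_F=float(mid),
                d_mean=d_final,
                d_ci=(d_final - half_final, d_final + half_final),
                n_reps=n_reps,
                history=history,
            )
        if d_mid > target_d:
            lo = mid
        else:
            hi = mid
    raise RuntimeError("calibration bisection did not converge")


# ---------------------------------------------------------------------------
# full experiments
# ---------------------------------------------------------------------------


@dataclass
class SimulatedExperiment:
    """A complete synthetic experiment with full provenance.

    ``trials`` holds one row per (participant, trial) including the
    generated observations, the true trial-wise parameter values
    (``true_<param>`` columns) and any neural signals (``F_<param>``);
    ``participants`` holds the baseline parameters.  ``regenerate()``
    rebuilds the experiment bit-identically from the stored seed/config.
    """

    trials: pd.DataFrame
    participants: pd.DataFrame
    config: dict
    seed: int

    def participant_trials(self, p: int) -> pd.DataFrame:
        return self.trials[self.trials["participant"] == p].reset_index(drop=True)

    def regenerate(self) -> "SimulatedExperiment":
        cfg = dict(self.config)
        if cfg.get("model") == "memory":
            from .fixtures import _memory_experiment

            return _memory_experiment(
                n_participants=cfg["n_participants"], n_trials=cfg["n_trials"], seed=self.seed
            )
        return simulate_experiment(seed=self.seed, **cfg)

    def save(self, directory) -> None:
        import pathlib

        path = pathlib.Path(directory)
        path.mkdir(parents=True, exist_ok=True)
        self.trials.to_csv(path / "trials.csv", index=False)
        self.participants.to_csv(path / "participants.csv", index=False)
        with open(path / "manifest.json", "w") as fh:
            json.dump({"seed": self.seed, "config": _jsonable(self.config)}, fh, indent=2)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def simulate_experiment(
    model: str = "hd",
    n_participants: int = 30,
    n_trials: int = 160,
    variability: Optional[dict] = None,
    input_noise: Optional[NoiseSpec] = None,
    neural: Optional[dict] = None,
    seed: int = 0,
    n_options: int = 2,
) -> SimulatedExperiment:
    """Generate a multi-participant experiment under the standard designs.

    ``variability`` maps parameter names to :class:`TrialwiseVariabilitySpec`
    (defaults: no trial-wise variability).  ``neural`` maps parameter names
    to noise SDs sigma_F for pseudo-neural signals tracking that parameter's
    true trial-wise values.  Participant ``p`` uses random stream
    ``(seed, p)``.
    """
    variability = variability or {}
    neural = neural or {}
    task = TaskConfig(n_trials=n_trials, n_options=n_options)
    frames = []
    part_rows = []
    for p in range(n_participants):
        rng = np.random.default_rng([seed, p])
        if model == "hd":
            base = sample_participants(1, ParticipantDistributions.hd(), rng).iloc[0]
            if n_options == 3:
                trials = generate_three_option_choiceset(base["kappa"], base["beta"], task, rng)
            else:
                trials = generate_choiceset(base["kappa"], task, rng)
            names = ("kappa", "beta")
            mdl = HDModel()
        elif model == "hdlba":
            base = sample_participants(1, ParticipantDistributions.hdlba(), rng).iloc[0]
            trials = generate_choiceset(base["kappa"], task, rng)
            names = ("kappa", "lambda_", "s", "b", "A", "t0")
            mdl = HDLBAModel()
        elif model == "lba":
            base = sample_participants(1, ParticipantDistributions.lba(), rng).iloc[0]
            trials = pd.DataFrame(index=range(n_trials))
            names = ("nu", "s", "b", "A", "t0")
            mdl = LBAModel()
        else:
            raise ValueError(f"unknown model {model!r}")

        theta = np.empty((n_trials, len(names)))
        for k, name in enumerate(names):
            if name in variability:
                spec = variability[name]
                lower = base["A"] if name == "b" and "A" in base else spec.lower
                spec = TrialwiseVariabilitySpec(
                    spec.parameter, spec.distribution, spec.sd, spec.range_, spec.level, lower, spec.upper
                )
                theta[:, k] = sample_trialwise(base[name], spec, n_trials, rng)
            else:
                theta[:, k] = base[name]

        utility_noise = None
        if input_noise is not None:
            inj = inject_noise(trials, input_noise, rng)
            gen_trials = inj.trials
            utility_noise = inj.utility_noise
        else:
            gen_trials = trials

        if model == "hd":
            sim = mdl.simulate(gen_trials, theta, rng, utility_noise=utility_noise)
        else:
            sim = mdl.simulate(gen_trials, theta, rng)
        # fitting sees the unperturbed task features
        for col in trials.columns:
            sim[col] = trials[col].to_numpy()
        for k, name in enumerate(names):
            sim[f"true_{name}"] = theta[:, k]
        for name, sigma_F in neural.items():
            sim[f"F_{name}"] = simulate_neural(sim[f"true_{name}"].to_numpy(), sigma_F, rng)
        sim["participant"] = p
        sim["trial"] = np.arange(n_trials)
        frames.append(sim)
        row = dict(base)
        row["participant"] = p
        part_rows.append(row)

    return SimulatedExperiment(
        trials=pd.concat(frames, ignore_index=True),
        participants=pd.DataFrame(part_rows),
        config={
            "model": model,
            "n_participants": n_participants,
            "n_trials": n_trials,
            "variability": variability,
            "input_noise": input_noise,
            "neural": neural,
            "n_options": n_options,
        },
        seed=seed,
    )
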
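# Methods

## The estimator

Leave-one-trial-out (LOTO) turns an ordinary maximum-likelihood fit into a
per-trial quantity. For a model with parameters θ fitted to *n* trials:

1. estimate all parameters on the full dataset (grid search for start
   values, then a bound-constrained simplex on the deviance −2·logL);
2. for every unit *t* (a trial, a block of trials, or an item's trial
   group), re-estimate only the parameter(s) of interest on the *n*−1
   remaining trials, holding every other parameter at its all-trial
   estimate and starting the refit from the all-trial estimates;
3. record the delta `θ̂(all) − θ̂(without t)`.

A unit whose behavior pulls the estimate above the participant's average
yields a positive delta. Deltas are *relative*: they carry the direction and
ranking of trial-wise fluctuations, not absolute parameter values, which is
exactly what a trial-level regressor for neural data requires. The *n*
refits are independent; the implementation solves them in lockstep with a
batched simplex so that one run of the method costs a few multiples of a
single fit.

For the Bernoulli/binomial toy model the whole construction is available in
closed form (delta `k/n − (k−k_t)/(n−m)`), and the pipeline uses the
analytic estimate, so the algebraic identities (deltas sum to zero; the
success/failure difference is `1/(n−m)`) hold exactly.

## Models

* **Binomial** — success probability θ; Fisher information `m/(θ(1−θ))`,
  so observations are most informative near the extremes.
* **Hyperbolic discounting (HD)** — utility `u = x/(1+κd)` with discount
  rate κ ∈ [0,1]; softmax choice rule with sensitivity β ≥ 0. The
  single-choice log-likelihood is monotone in κ (the analytic score is
  positive after an immediate choice, negative after a delayed one), so κ
  is interior-identified only once both options have been chosen; for a
  repeated trial chosen n_i/n_j times the MLE has the closed form
  `κ = (β x_j /(β x_i + ln(n_j/n_i)) − 1)/d_j`.
* **HD-LBA** — the same utilities drive a two-accumulator linear ballistic
  accumulator through drift means `v_i = 1/2 + λ(u_i − u_j)`, `v_j = 1 −
  v_i`. Response times then carry information about the trial's discount
  rate beyond the choice itself. The defective density is the standard LBA
  form; trials on which both sampled drifts are non-positive are resampled
  in the simulator, and the density is normalized by `1 − P(all drifts ≤ 0)`
  so the generative process and the likelihood describe the same
  distribution.
* **Memory-based diffusion** — choices after a fixed deliberation window
  *t* follow `Φ(Δ_V t/σ)` with `Δ_V = M_l(V_l−g) − M_r(V_r−g)`; the recall
  probability *M* is α or β depending on whether the item was encoded once
  or twice, and the bias *g* is a per-subject input constant. Item-level
  LOTO removes the (three) trials offering an item and re-estimates the
  memory parameters.

## Estimation engine

Start values come from a deterministic cartesian grid over the free
parameters. Grid resolutions follow the two-tier convention: 25 points per
parameter for the HD model, 15 points for the participant-varying HD-LBA
parameters (κ, b) and 3 for the shared nuisance parameters. The grid spans
an empirically plausible range where the formal bound is much wider than
the scale of the likelihood (e.g. κ is searched on [0, 0.1] although the
bound is [0, 1]); otherwise a 25-point grid over [0, 1] strands the simplex
in a local minimum far from any realistic discount rate. The memory model
uses ten random restarts instead of a grid, with restart *r* seeded by the
sequence `(rng_seed, r)`.

The simplex is the classic Nelder-Mead recursion (coefficients 1, 2, 0.5,
0.5). Bounds are enforced by scoring infeasible candidates +inf, so the
simplex stays inside the box and approaches boundary optima from within
(projection clipping can collapse the simplex onto a face and stall short
of a near-boundary interior optimum — this failure mode is covered by a
regression test). Convergence requires both the deviance spread and the
vertex spread to fall below the tolerance, 1e-13 by default. The strict
default matters: leave-out refits must resolve deviance differences caused
by a single trial, which shrink as 1/n; with a lenient 1e-4 tolerance and
~1,600 trials the leave-out estimates visibly quantize into ties. Deviance
sums inside the compiled likelihood kernels use Kahan compensation because
the smallest resolvable leave-out improvements sit only a few ulp above the
total deviance.

Two documented relaxations exist for the simulation-heavy modules (power
analysis, large replication loops): deviance tolerance 1e-6 with the vertex
spread left to the curvature (`x_tolerance = inf`). Deltas computed this
way agree with the strict default to well under 0.1% of a delta standard
deviation while using a fraction of the iterations; this was verified
directly and is a pure runtime choice.

Warm-started refits use a reduced initial simplex (10⁻³ relative) because
the n−1 optimum lies within O(1/n) of the all-trial estimate.

## Synthetic study conditions

The generator reproduces a standard adaptive intertemporal-choice design:
immediate option fixed at 20 units, delayed amounts on a 0.5-unit grid in
[20.5, 80], delays from {1, 7, 14, 30, 90, 180, 270, 360} days. A candidate
choice set is accepted when the immediate option has the higher utility in
45–55% of trials under the participant's baseline κ; after 1,000 failed
attempts the window widens by 5 points per side. Near the lower κ
truncation bound several relaxations are always needed; generation still
terminates because the window eventually covers [0, 1]. The three-option
variant sorts three amounts and delays so one option is smallest in both
and one largest in both, and resamples whole sets (criterion +0.001 per
round) until no option's mean softmax probability exceeds 0.34.

Participant baselines: κ ~ log-normal(−4.8, 1) truncated to [0.001, 0.07]
and β ~ log-normal(−0.77, 0.71) truncated to [0.01, 10] (right-skewed, as
empirical discount-rate samples are); HD-LBA uses the same κ law, b ~
U[2, 3], and constants λ = 0.1, s = 0.3, A = 1, t₀ = 0.5; the plain LBA
study draws ν ~ N(0.6, 0.02), s ~ N(0.2, 0.02), A ~ N(1, 0.1) with A ≤ b,
b = 1.5, t₀ = 0.2 (settings that keep accuracies in roughly 53–89% and
mean RTs in 1.5–2.1 s). Truncation is by rejection.

Trial-wise variability is Gaussian around the baseline, truncated at zero
(and at b ≥ A for the threshold), with a level multiplier for the 10–100%
grids. Defaults: κ_t SD 0.01 and, for the two-parameter threshold
analyses, b_t SD 0.4. The threshold value deserves a note: at an SD of
0.04 a 160-trial experiment carries essentially no per-trial information
about b (the recovery correlation is indistinguishable from zero for any
estimator), whereas 0.4 matches the SD-equivalent uniform range (1.4 =
0.4·√12) used in the distribution-invariance experiments, yields a
calibrated threshold-signal noise level near 5, and makes threshold
recovery non-trivial (r ≈ 0.35–0.45). We therefore treat 0.4 as the
effective study condition for every analysis that infers threshold
variability.

Input/output noise adds Gaussian perturbations to the delayed amount
(max SD 9), delay (max SD 10, clamped positive, left continuous rather than
snapped back to the delay grid) or computed utility (max SD 6) at
generation time only — the analyst-side trial table keeps the clean
features, which is the point of the misattribution analyses. The
κ-noise-equivalent utility variance depends strongly on the baseline
discount rate (from ~3 to ~150 squared units across the sampled baselines);
the utility-noise maximum sits inside that range rather than matching any
single baseline.

Pseudo-neural signals are `F_t ~ Normal(π_t, σ_F)` for a target parameter's
true trial-wise values π_t. σ_F is calibrated so that, regressing F on the
standardized true π_t plus the observations within each participant, the
group-level Cohen's d of the π_t coefficient equals 1 (bracketing bisection
in log σ; a candidate is accepted when the 95% CI of the mean d over the
replicate experiments covers the target). For the 30 × 160 designs this
yields σ_F ≈ 0.10 for κ (choice-only and RT designs alike) and ≈ 5 for the
threshold. Any textbook reading of this procedure pins σ_F near
SD(π_t)·√n_trials, so these values are an internal property of the d = 1
condition; downstream power results depend only on that condition, not on
the absolute σ_F scale.

Reproducibility: a master seed spawns per-participant streams `(seed, p)`
and per-replicate streams `(seed, rep, p)`; every `SimulatedExperiment`
regenerates bit-identically from its stored seed and config.

## Variability-presence test

Fitting n−1 trials improves the fit for two reasons: one trial less to
explain, and the parameter adjusting to the retained trials. The test
statistic keeps only the second part: the mean over leave-out steps of the
deviance improvement *on the retained trials* (non-negative by
construction because each refit starts at the all-trial estimates). The
null distribution comes from re-simulating the experiment at the fitted
parameters with no trial-wise variability, re-fitting, and re-running the
pipeline; rejection means the observed statistic exceeds the 95th
percentile of the null draws. No distributional assumption is involved.
Degenerate units (an option chosen fewer than two times overall, whose
leave-out estimate escapes the admissible range) are flagged and excluded
identically in both branches. The mean (rather than the sum) over steps is
used; the two differ by a constant factor and lead to identical decisions.

## Power and specificity

Each replicate simulates the full two-parameter HD-LBA experiment with
trial-wise κ_t and b_t, one calibrated neural signal per parameter, runs
the complete fit + LOTO pipeline, and regresses each signal on the
standardized LOTO deltas of *both* parameters plus choice and RT within
each participant, followed by a group one-sample t-test per coefficient
(the same two-stage logic as a GLM group analysis). Sensitivity is the
fraction of replicates in which a signal's own parameter is significant at
two-sided p < .05; the false-positive rate is the fraction in which the
other parameter is. In the scaled fitting mode the all-trial fit frees
(κ, b, λ, s) and keeps (A, t₀) at the design constants; freeing the
drift-scale parameters is essential — with λ and s frozen, a single
extreme-RT trial can dominate the likelihood and crush every other unit's
delta (observed directly during development). `estimate_nuisance=True`
restores full six-parameter estimation at several times the cost.

Desk-scale defaults used by the test suite: 100 replicate experiments at
the full 30 × 160 design for power; 200 null replicates for the
variability test. At these scales the sensitivity for κ lands near its
large-replicate value; threshold sensitivity is lower than the κ value
(~0.4 at the scaled fitting mode) because threshold deltas recover b_t at
r ≈ 0.35 and share variance with the RT covariate.

## What the simulations do and do not show

All validation rests on data generated by the models themselves under the
stated conditions. Passing tests therefore demonstrate internal
consistency — the estimator recovers what the generative process planted,
at the stated design sizes — not that any real dataset satisfies the
models' assumptions (no lapses, stationary baselines, correctly specified
response process, Gaussian trial-wise variability). The misattribution
analyses cover only the perturbations implemented here; a new model, task,
or parameter set needs its own simulation study before LOTO estimates are
linked to neural data.

## Known limitations

* Choice-only models separate deltas strictly by choice; trials whose
  leave-out shift falls below double-precision deviance resolution come
  back as exact-zero ties (a handful per 160 trials when the fitted
  sensitivity is low).
* The closed-form κ can exceed the [0, 1] bound for extreme premiums;
  numerical estimation clamps at the bounds and reports boundary fits
  rather than silently clipping closed forms.
* Recovery of threshold variability is intrinsically weak per trial; block
  or item grouping, more trials, or stronger variability are the remedies.
* Deep likelihood tails (survival terms of nearly-finished accumulators)
  lose relative precision to cancellation; the compiled and reference
  implementations agree to 1e-6 only away from the 1e-300 floor.
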
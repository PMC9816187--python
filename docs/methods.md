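# Methods

`devaltask` models a four-phase instrumental learning and devaluation task
(a "slips-of-action" paradigm). Participants first learn, by trial and
error, which of two button presses (left/right) opens each of six boxes
(discriminative stimuli) for a distinct reward picture (outcome) plus
points; they are then tested on outcome–action knowledge, and finally must
repeatedly withhold responses when either specific *outcomes*
(slips-of-action test) or specific *stimuli* (baseline test) are declared
worthless. The package provides the task generator, two computational
models of choice, per-subject maximum-likelihood fitting and model
comparison, a synthetic-cohort generator, and the group-level statistical
layer.

## Task structure

* Learning phase: 6 blocks × 12 trials; each stimulus appears twice per
  block in randomized order. Correct responses earn points; faster correct
  responses within the 2-s window earn more (0–5). Incorrect or omitted
  responses earn nothing. This is the only phase with feedback.
* Outcome–action test: 12 trials; each trial shows one left-earned and one
  right-earned outcome with one crossed out; the correct response is the one
  that earned the still-valued outcome. Each outcome is crossed out exactly
  twice.
* Slips-of-action and baseline tests: 9 blocks × 12 trials each, in
  counterbalanced order, in nominal extinction (no feedback). An
  instruction screen before each block devalues two outcomes (slips) or two
  stimuli (baseline); every item is devalued in exactly 3 of the 9 blocks.
  The per-block devaluation pairs are built from three randomly chosen
  perfect matchings of the one-factorization of K6, which guarantees the
  3-regular marginal counts by construction.
* Counterbalancing: 120 arrangements = 20 choices of which three stimuli
  take the left response × 6 cyclic rotations of the stimulus→outcome
  bijection. Across arrangements every stimulus is paired with both
  responses and all six outcomes.

A `validate_schedule` pass re-derives every structural constraint and
returns named violations; the generator's output is validated in tests for
arbitrary seeds.

## Reinforcement-learning model (learning phase only)

Per stimulus j and response a, values follow the delta rule
`V[j,a] += alpha * (O - V[j,a])` with learning rate `alpha` in [0,1]. The
outcome `O` is either the points actually received (`rt_dependent`,
`O = 5(1 - rt/2000)` for correct responses) or a constant 5 (`fixed`).
Choices use a softmax with a perseveration term:

    p(left) = logistic(beta_t (V_left - V_right) + tau_t * rep),

`rep` = +1/−1/0 for a previous left/right/no previous response to that
stimulus. Both weights drift log-linearly over the normalized trial index,
`beta_t = beta0 exp(beta_slope t/T)`, `tau_t = tau0 exp(tau_slope t/T)`.
The exact dynamic form of the time-varying softmax was an open design
point; the log-linear drift was chosen as the minimal monotone,
sign-preserving two-parameter form. Likewise the linear RT→points map is
the least-structured choice consistent with "faster is worth more" on a
0–5 scale. Values start at 0 (no prior reward experience); omitted
responses contribute no likelihood term and leave values and perseveration
state unchanged. The model is not applied to the test phases: without
feedback there is no outcome signal to update values.

## Bayesian belief-updating model (all four phases)

For each stimulus the observer tracks three categorical beliefs: which
response is rewarded (binary), whether responding at all pays
(go-rewarded vs no-go-correct, binary), and which of the six outcomes the
stimulus yields. Each piece of categorical evidence multiplies the prior
by a two-point likelihood — `lam` for the consistent hypothesis, `(1-lam)`
shared equally among inconsistent ones — and renormalizes. The single
subject parameter `lam` in (0.5, 1) is the pace of belief update. On the
binary hypothesis sets `lam = 0.5` is an exact fixed point; for the 6-way
outcome belief the uninformative point of this parameterization is 1/6,
so outcome beliefs still sharpen at `lam = 0.5` (a property of the chosen
likelihood, noted here deliberately).

Between the learning phase and each devaluation test, every belief decays
toward uniform by a fixed mixing weight (0.5, identical for all subjects,
exposed as configuration). During the tests, beliefs change only at
instruction screens. A baseline instruction is direct evidence of strength
`lam` that the two named stimuli are no-go and the remaining stimuli are
go. A slips-of-action instruction names outcomes, so its force on each
stimulus is marginalized through the outcome belief (Bayesian inversion):
with devaluation probability `d = sum over devalued outcomes of
P(outcome | stimulus)`, the go/no-go likelihoods interpolate between the
certain-devalued and certain-valued cases, `L(go) = d(1-lam) + (1-d)lam`.

Instructions declare the *current* status of each item. They therefore
replace the previous block's update rather than compounding with it: each
block's odds factor is applied relative to the stimulus's post-decay base
belief, which is equivalent to applying a devaluing update when an item
enters the devalued set and one symmetric revaluing update when it leaves.
The alternative — accumulating a fresh "valued" update for every valued
stimulus in every block — makes go-beliefs saturate at odds `(lam/(1-lam))^k`
after k valued blocks, so that a later devaluation instruction can no
longer suppress responding and, perversely, faster updaters respond *more*
to devalued stimuli. The replacement rule preserves the intended
mechanism: the devalued-response rate decreases monotonically in `lam`.

Choices are probability matching with a small fixed lapse (0.02):
`p(go) = (1-lapse) P(go-rewarded) + lapse/2`, and conditional on going,
`p(left) = P(left-rewarded)`. In the outcome–action test the response
probability comes from inverting outcome and response beliefs:
`b_a = sum_j P_j(valued outcome) P_j(a rewarded)`. Non-responses in the
test phases are scored as deliberate no-go choices. The decay weight,
lapse, and belief→choice rule are fixed rather than fitted so that group
contrasts concentrate on `lam`; the outcome–action test contributes to the
likelihood by default (configurable via the phase set).

The likelihood is implemented twice on purpose: once through the public
single-step operations (readable, used by the simulators) and once as an
incremental replay on plain floats (used by the fitting loop, roughly an
order of magnitude faster). A dedicated test holds the two routes to
1e-10 agreement on full four-phase datasets.

## Fitting and model comparison

Per-subject bounded maximum likelihood via Powell restarts (10 by
default; the first start at the box midpoint, the rest drawn uniformly
inside the bounds from a seeded generator). Bounds: `alpha` [0,1],
`beta0` [0,20], slopes [−3,3], `tau0` [−5,5], `lam` [0.501, 0.999].
Model comparison on the learning phase uses BIC (`k ln n − 2 ln L`), ties
to the model with fewer parameters. The RL model has five free parameters,
the Bayesian model one.

Recovery studies simulate agents with parameters drawn from declared
uniform priors, refit them, and report Spearman correlations between true
and recovered values. Parameters the study does not vary are held at
known design values and pinned during fitting: the study then measures
how well the likelihood identifies the varied parameter under a known
design. Joint recovery of all five RL parameters from 72 binary choices
is weakly identified (the learning rate trades off against the
exploration weight) — a known limitation stated rather than hidden. For
learning-rate recovery the design uses the fixed-outcome variant (no
reward noise) with `beta0 = 0.8, beta_slope = 1.2, tau0 = 0`: the low,
rising exploration weight keeps choice probabilities mid-range while
values grow, which is where binary choices carry the most information
about the learning rate. Even so, the rank correlation attainable from 72
trials over `alpha ~ U(0.05, 0.6)` is about 0.75 on average: above ~0.3
the acquisition curve saturates within a couple of trials per stimulus
and the likelihood flattens, so maximum-likelihood estimates of large
learning rates sometimes run to the boundary.

For the learning-phase model comparison, agents are drawn from a regime
with strong perseveration (`tau0 ~ U(1.5, 3)`): repetition streaks are the
choice structure the Bayesian observer cannot express, so they make the
comparison informative, mirroring the empirical observation that human
learners perseverate.

## Synthetic cohorts

No participant data ship with the package; every analysis runs on
simulated cohorts of two groups (healthy-control-like HC and
bulimia-nervosa-like BN, 30 subjects each by default). Each subject's
learning phase is simulated by the RL agent with parameters drawn from
uniform ranges chosen to produce gradual, noisy acquisition plateauing
near 96% final-block accuracy — the profile typical of human learners on
this task. The test phases are simulated by the Bayesian observer: each
test replays the subject's actual learning-phase experience with the
`lam` that governs that test (matching how the model is fitted per phase)
and then responds by probability matching.

Per subject, two pace-of-update parameters (`lam_slips`,
`lam_baseline`) are drawn from Beta distributions rescaled to
(0.55, 0.95) (concentration 10, so SD ≈ 0.06) via a Gaussian copula —
correlated 0.3 in HC, uncorrelated in BN. The group difference is
injected only into the baseline-test `lam` (BN mean 0.08 lower by
default); its magnitude is a tunable stand-in, not an estimate, since no
interpretable effect size is available. Binge and vomit counts over three
months are negative-binomial with `log mu = intercept − 4 lam_baseline`
and NB2 dispersion 0.6; the intercepts (6.8, 7.0) put mean counts near 45
and 55 at `lam = 0.75`, the scale of symptom frequencies reported for
moderately ill outpatient samples. The same generative link is applied to
both groups — a synthetic simplification (real controls report no bulimic
episodes) that keeps the symptom regressions well-defined cohort-wide.
Reaction times are `700 − 400 (certainty − 0.5) + N(0, 150)` ms truncated
to (0, 2000], with certainty `2|p − 0.5|` of the generating choice
probability, so confident choices are faster and fitted `lam` predicts
valued-trial RT negatively, as intended.

What the generator does *not* emulate: demographics and clinical
covariates beyond the two symptom counts, fatigue and attention drift,
within-session RT autocorrelation, instruction misunderstanding, or any
model-misspecified behavior — cohorts are generated by the same model
families that are fitted. Passing pipeline tests therefore show that the
analysis chain is correct and adequately powered under the assumed
generative structure, not that the models fit real humans.

## Statistical layer

* Devaluation sensitivity index (DSI): percent of valued trials with a
  registered response minus percent of devalued trials with one, computed
  over all scheduled trials (omission = no response, since the tests score
  withholding). Higher = more flexible.
* Group × valuation: linear mixed model of response percentages (per
  subject × valuation × test half; halves give within-subject replication)
  on group, valuation, and their interaction with a subject random
  intercept *and* a subject random valuation slope, via statsmodels MixedLM
  (BFGS with fallback optimizers). The random slope matters: subjects
  genuinely differ in how strongly devaluation suppresses their responding
  (their pace of update varies), and with an intercept-only structure the
  interaction Wald test rejected true nulls about three times too often in
  calibration runs; adding the slope restores the nominal 5% rate. The
  reported contract is the interaction estimate, t, and p, plus post-hoc
  valued-only and devalued-only rank-sum contrasts, reported uncorrected
  by default (Holm correction available in the caller). The
  response-variable granularity (halves rather than blocks) is a default,
  not a claim.
* Fitted-parameter group comparisons: Wilcoxon rank-sum
  (scipy `mannwhitneyu`, two-sided), reporting W, medians, and the
  rank-biserial effect size; an all-ties input is flagged and returns p = 1.
* Symptom regressions: negative-binomial (log link) with a single
  predictor (DSI or `lam`), statsmodels discrete NB with estimated
  dispersion. All-zero counts raise; a constant predictor reports an
  undefined slope rather than a spurious one.
* RT cross-check: Huber robust regression (statsmodels RLM) of per-subject
  mean valued-trial RT on fitted `lam`.
* Collapsed analysis: the same mixed-model contract with both tests folded
  into one response pool.

## Numerical choices and degenerate inputs

Probabilities in the hot likelihood path are clamped to [1e-12, 1−1e-12]
before odds are formed, which matters only when the decay weight is set
to 0 and beliefs saturate. Powell's line search can overshoot box bounds
by rounding error; candidate parameters are clipped back inside before
evaluation. Blocks with no registered response report accuracy as NaN
with an explicit flag. Trial tables are stably sorted by (block, trial)
before any likelihood evaluation, making fits invariant to row order.
Seeds derived from a master seed stay below 2^31.

## Problem sizes

Default analysis scales, chosen as the package's standard validation
sizes: recovery studies use 40 agents; model comparison 40 agents;
power/type-I studies of the headline contrasts use 50 effect cohorts and
100 null cohorts of 30 subjects per group; mechanism monotonicity uses
100–200 agents per `lam` level.

## Known limitations

* The likelihood parameterization, decay form, and belief→choice rule of
  the Bayesian observer are this package's documented defaults; other
  reasonable choices exist for each, and quantitative conclusions can be
  sensitive to them.
* The learning-rate recovery ceiling (~0.75 rank correlation) discussed
  above.
* The synthetic effect size for the group difference in `lam` is a
  configurable assumption; power statements are relative to it.
* The mixed model uses a Wald t on the interaction rather than the
  likelihood-ratio form; with 60 subjects the two agree closely.
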
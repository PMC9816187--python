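"""Synthetic cohorts with the statistical structure the analyses assume.

No participant data are distributed with this package, so every pipeline
stage runs on simulated cohorts: two groups (healthy controls, HC, and a
bulimia-nervosa-like group, BN) of ~30 subjects each.  Each subject

* learns the task with the reinforcement-learning agent (the model that best
  describes the feedback-driven learning phase), and
* performs the outcome-action, slips-of-action and baseline tests with the
  Bayesian observer, with subject-specific pace-of-update parameters.

The group difference is injected only into the lambda governing
baseline-test updating (mean shift ``delta`` lower in BN); the two lambdas
per subject are correlated in HC and uncorrelated in BN.  Binge and vomit
counts over three months are negative-binomially distributed with log-mean
decreasing in the baseline-test lambda, and reaction times decrease with
choice certainty — so the symptom regressions and the RT cross-check have a
recoverable generative signal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from . import bayes_model, rl_model, task_schedule
from .bayes_model import BayesParams, BeliefState, InstructionEvent
from .rl_model import RLParams
from .task_schedule import N_COUNTERBALANCE, TaskSchedule, generate_schedule

TRIAL_COLUMNS = [
    "subject", "group", "phase", "block", "trial", "stimulus", "devalued_items",
    "trial_devalued", "valued_outcome", "crossed_out_outcome",
    "response", "rt_ms", "outcome_id", "points", "correct",
]
VALID_RESPONSES = {"left", "right", "none"}


@dataclass(frozen=True)
class RTModel:
    """Linear certainty -> reaction-time map with Gaussian noise.

    rt = base + slope * (certainty - 0.5) + N(0, sd), truncated to
    (0, 2000] ms.  ``certainty`` is 2*|p - 0.5| of the generating choice
    probability, so confident choices are faster (slope is negative).
    """

    base_ms: float = 700.0
    certainty_slope_ms: float = -400.0
    noise_sd_ms: float = 150.0

    def sample(self, certainty: float, rng: np.random.Generator) -> float:
        rt = self.base_ms + self.certainty_slope_ms * (certainty - 0.5) + rng.normal(0.0, self.noise_sd_ms)
        return float(min(max(rt, 1.0), task_schedule.RESPONSE_WINDOW_MS))


@dataclass(frozen=True)
class LambdaSpec:
    """Group distributions of the pace-of-update parameter.

    Lambdas are Beta-distributed, rescaled to (lo, hi); the BN baseline-test
    mean sits ``delta`` below the HC mean, the slips-of-action mean is
    common.  ``corr_*`` is the Gaussian-copula correlation between a
    subject's two lambdas.
    """

    hc_mean: float = 0.80
    delta: float = 0.08
    lo: float = 0.55
    hi: float = 0.95
    concentration: float = 10.0
    corr_hc: float = 0.3
    corr_bn: float = 0.0

    def sample_pair(self, group: str, rng: np.random.Generator) -> tuple[float, float]:
        """(lam_slips, lam_baseline) for one subject."""
        base_mean = self.hc_mean - (self.delta if group == "BN" else 0.0)
        rho = self.corr_hc if group == "HC" else self.corr_bn
        z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]])
        u = stats.norm.cdf(z)
        out = []
        for mean, ui in zip((self.hc_mean, base_mean), u):
            m01 = (mean - self.lo) / (self.hi - self.lo)
            a, b = m01 * self.concentration, (1.0 - m01) * self.concentration
            out.append(self.lo + (self.hi - self.lo) * float(stats.beta.ppf(ui, a, b)))
        return out[0], out[1]


@dataclass(frozen=True)
class RLPriors:
    """Uniform ranges the learning-phase agent parameters are drawn from.

    The defaults produce gradual, noisy acquisition that plateaus near 96%
    final-block accuracy — the profile typical of human learners on this
    task — rather than the abrupt, error-free convergence that large
    exploration weights would give.
    """

    alpha: tuple[float, float] = (0.1, 0.4)
    beta0: tuple[float, float] = (0.6, 1.2)
    beta_slope: tuple[float, float] = (0.5, 1.0)
    tau0: tuple[float, float] = (0.3, 1.0)
    tau_slope: tuple[float, float] = (-0.3, 0.3)

    def sample(self, rng: np.random.Generator, pe_variant: str = "rt_dependent") -> RLParams:
        return RLParams(
            alpha=float(rng.uniform(*self.alpha)),
            beta0=float(rng.uniform(*self.beta0)),
            beta_slope=float(rng.uniform(*self.beta_slope)),
            tau0=float(rng.uniform(*self.tau0)),
            tau_slope=float(rng.uniform(*self.tau_slope)),
            pe_variant=pe_variant,
        )


# Regime for the learning-phase model comparison: perseveration is the
# structure the Bayesian observer cannot express, so agents whose choices
# carry a strong repetition streak make the comparison informative.
COMPARISON_RL_PRIORS = RLPriors(
    alpha=(0.1, 0.4),
    beta0=(0.6, 1.2),
    beta_slope=(0.5, 1.0),
    tau0=(1.5, 3.0),
    tau_slope=(0.0, 0.5),
)


@dataclass(frozen=True)
class SymptomLink:
    """Negative-binomial symptom counts with log-mean linear in lambda.

    log E[count] = intercept + slope * lam_baseline; ``dispersion`` is the
    NB2 alpha (variance mu + alpha mu^2).  The negative slope makes slower
    updaters (smaller lambda) report more episodes.
    """

    binge_intercept: float = 6.8
    vomit_intercept: float = 7.0
    slope: float = -4.0
    dispersion: float = 0.6

    def sample(self, lam: float, rng: np.random.Generator) -> tuple[int, int]:
        counts = []
        for intercept in (self.binge_intercept, self.vomit_intercept):
            mu = math.exp(intercept + self.slope * lam)
            shape = 1.0 / self.dispersion
            counts.append(int(rng.poisson(rng.gamma(shape, mu / shape))))
        return counts[0], counts[1]


@dataclass(frozen=True)
class CohortSpec:
    n_per_group: int = 30
    lambda_spec: LambdaSpec = field(default_factory=LambdaSpec)
    rl_priors: RLPriors = field(default_factory=RLPriors)
    symptom_link: SymptomLink = field(default_factory=SymptomLink)
    rt_model: RTModel = field(default_factory=RTModel)
    lapse: float = bayes_model.DEFAULT_LAPSE
    decay_weight: float = bayes_model.DEFAULT_DECAY
    pe_variant: str = "rt_dependent"
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.symptom_link.dispersion <= 0:
            raise ValueError("symptom dispersion must be > 0")


@dataclass
class SubjectDataset:
    subject: str
    group: str
    schedule: TaskSchedule | None
    trials: pd.DataFrame
    binge_count_3mo: int
    vomit_count_3mo: int
    true_params: dict[str, float] = field(default_factory=dict)


def _trial_devalued(schedule: TaskSchedule, spec, cmap) -> bool:
    if spec.phase == "baseline":
        return spec.stimulus in spec.devalued
    return cmap.stimulus_outcome[spec.stimulus] in spec.devalued


def _simulate_phase2(schedule, state: BeliefState, params: BayesParams, rng, rt_model, rows):
    cmap = schedule.contingencies
    for t in schedule.phase_trials("outcome_action"):
        lo, ro = t.outcome_pair
        valued = ro if t.crossed_out == lo else lo
        p_left = bayes_model.phase2_choice_probability(state, valued, params)
        response = "left" if rng.random() < p_left else "right"
        rt = rt_model.sample(2.0 * abs(p_left - 0.5), rng)
        correct = cmap.outcome_response[valued] == response
        rows.append({
            "phase": "outcome_action", "block": t.block, "trial": t.trial, "stimulus": np.nan,
            "devalued_items": "", "trial_devalued": 0, "valued_outcome": float(valued),
            "crossed_out_outcome": float(t.crossed_out), "response": response, "rt_ms": rt,
            "outcome_id": np.nan, "points": np.nan, "correct": int(correct),
        })


def _simulate_test(schedule, phase: str, base_state: BeliefState, params: BayesParams,
                   decay_weight: float, rng, rt_model, rows):
    cmap = schedule.contingencies
    state = bayes_model.decay_beliefs(base_state, decay_weight)
    current_block = None
    for t in schedule.phase_trials(phase):
        if t.block != current_block:
            state = bayes_model.apply_instruction(
                state, InstructionEvent(phase, t.devalued, t.block), params
            )
            current_block = t.block
        p_go_left, p_go_right, p_nogo = bayes_model.response_probability(state, t.stimulus, phase, params)
        u = rng.random()
        if u < p_go_left:
            response = "left"
        elif u < p_go_left + p_go_right:
            response = "right"
        else:
            response = "none"
        devalued = _trial_devalued(schedule, t, cmap)
        p_go = p_go_left + p_go_right
        rt = rt_model.sample(2.0 * abs(p_go - 0.5), rng) if response != "none" else np.nan
        if devalued:
            correct = response == "none"
        else:
            correct = response == cmap.stimulus_response[t.stimulus]
        rows.append({
            "phase": phase, "block": t.block, "trial": t.trial, "stimulus": float(t.stimulus),
            "devalued_items": ";".join(str(i) for i in sorted(t.devalued)),
            "trial_devalued": int(devalued), "valued_outcome": np.nan, "crossed_out_outcome": np.nan,
            "response": response, "rt_ms": rt, "outcome_id": np.nan, "points": np.nan,
            "correct": int(correct),
        })


def simulate_bayes_subject(
    schedule: TaskSchedule,
    lam: float,
    rng_seed: int,
    lapse: float = bayes_model.DEFAULT_LAPSE,
    decay_weight: float = bayes_model.DEFAULT_DECAY,
    rt_model: RTModel | None = None,
) -> pd.DataFrame:
    """Simulate a single-lambda Bayesian agent through all four phases.

    Used for parameter recovery: the same lambda drives learning-phase
    observation, both devaluation tests and the outcome-action test.
    """
    rt_model = rt_model or RTModel()
    rng = np.random.default_rng(rng_seed)
    params = BayesParams(lam=lam, lapse=lapse)
    cmap = schedule.contingencies
    state = BeliefState()
    rows = []
    for t in schedule.phase_trials("learning"):
        s = t.stimulus
        p_left = (1.0 - lapse) * state.response_belief[s, 0] + lapse / 2.0
        response = "left" if rng.random() < p_left else "right"
        rt = rt_model.sample(2.0 * abs(p_left - 0.5), rng)
        correct = response == cmap.stimulus_response[s]
        points = rl_model.trial_outcome(correct, rt, "rt_dependent")
        outcome_id = cmap.stimulus_outcome[s] if correct else None
        state = bayes_model.observe_learning_trial(state, s, response, outcome_id, points > 0, params)
        rows.append({
            "phase": "learning", "block": t.block, "trial": t.trial, "stimulus": float(s),
            "devalued_items": "", "trial_devalued": 0, "valued_outcome": np.nan,
            "crossed_out_outcome": np.nan, "response": response, "rt_ms": rt,
            "outcome_id": np.nan if outcome_id is None else float(outcome_id),
            "points": points, "correct": int(correct),
        })
    _simulate_phase2(schedule, state, params, rng, rt_model, rows)
    for phase in ("slips_of_action", "baseline") if schedule.test_order == "slips_first" else ("baseline", "slips_of_action"):
        _simulate_test(schedule, phase, state, params, decay_weight, rng, rt_model, rows)
    return pd.DataFrame(rows)


def generate_subject(
    subject: str,
    group: str,
    spec: CohortSpec,
    schedule: TaskSchedule,
    rng: np.random.Generator,
) -> SubjectDataset:
    """One synthetic subject: RL learning phase, Bayesian test phases."""
    rl_params = spec.rl_priors.sample(rng, spec.pe_variant)
    lam_slips, lam_baseline = spec.lambda_spec.sample_pair(group, rng)
    phase1 = rl_model.simulate_learning(schedule, rl_params, int(rng.integers(2**31)), spec.rt_model)
    phase1 = phase1.assign(valued_outcome=np.nan, crossed_out_outcome=np.nan)

    rows: list[dict] = []
    # Each test replays the learning phase with the lambda that governs that
    # test, mirroring how the model is fitted per phase.
    p_slips = BayesParams(lam=lam_slips, lapse=spec.lapse)
    p_base = BayesParams(lam=lam_baseline, lapse=spec.lapse)
    state_slips = bayes_model.replay_phase1(phase1, p_slips)
    state_base = bayes_model.replay_phase1(phase1, p_base)
    _simulate_phase2(schedule, state_slips, p_slips, rng, spec.rt_model, rows)
    _simulate_test(schedule, "slips_of_action", state_slips, p_slips, spec.decay_weight, rng, spec.rt_model, rows)
    _simulate_test(schedule, "baseline", state_base, p_base, spec.decay_weight, rng, spec.rt_model, rows)
    trials = pd.concat([phase1, pd.DataFrame(rows)], ignore_index=True)
    trials.insert(0, "group", group)
    trials.insert(0, "subject", subject)

    binge, vomit = spec.symptom_link.sample(lam_baseline, rng)
    true_params = {f"true_{k}": v for k, v in asdict(rl_params).items() if k != "pe_variant"}
    true_params.update({"true_lam_slips": lam_slips, "true_lam_baseline": lam_baseline})
    return SubjectDataset(subject, group, schedule, trials, binge, vomit, true_params)


def generate_cohort(spec: CohortSpec) -> list[SubjectDataset]:
    """Generate a full two-group cohort; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    cohort = []
    idx = 0
    for group in ("HC", "BN"):
        for i in range(spec.n_per_group):
            schedule = generate_schedule(
                seed=int(rng.integers(2**31)),
                counterbalance_id=idx % N_COUNTERBALANCE,
                test_order="slips_first" if idx % 2 == 0 else "baseline_first",
            )
            cohort.append(generate_subject(f"{group.lower()}{i + 1:03d}", group, spec, schedule, rng))
            idx += 1
    return cohort


def cohort_frames(cohort: list[SubjectDataset]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(trial-level, subject-level) tidy tables for a cohort."""
    trials = pd.concat([s.trials for s in cohort], ignore_index=True)
    subjects = pd.DataFrame(
        [
            {"subject": s.subject, "group": s.group,
             "binge_count_3mo": s.binge_count_3mo, "vomit_count_3mo": s.vomit_count_3mo,
             **s.true_params}
            for s in cohort
        ]
    )
    return trials, subjects


def write_trials(cohort: list[SubjectDataset], trials_path, subjects_path) -> None:
    trials, subjects = cohort_frames(cohort)
    trials = trials.reindex(columns=TRIAL_COLUMNS)
    trials.to_csv(trials_path, index=False)
    subjects.to_csv(subjects_path, index=False)


class TrialParseError(ValueError):
    pass


def _validate_trials(trials: pd.DataFrame) -> None:
    bad = ~trials["response"].fillna("none").isin(VALID_RESPONSES)
    if bad.any():
        line = int(trials.index[bad][0]) + 2  # header + 1-based
        raise TrialParseError(
            f"line {line}: invalid response {trials.loc[trials.index[bad][0], 'response']!r} "
            f"(expected one of {sorted(VALID_RESPONSES)})"
        )
    for col in ("rt_ms", "points"):
        coerced = pd.to_numeric(trials[col], errors="coerce")
        malformed = coerced.isna() & trials[col].notna() & (trials[col] != "")
        if malformed.any():
            line = int(trials.index[malformed][0]) + 2
            raise TrialParseError(f"line {line}: non-numeric value in column {col!r}")
    extinction = trials["phase"].isin(["slips_of_action", "baseline"])
    fed_back = extinction & (
        pd.to_numeric(trials["outcome_id"], errors="coerce").notna()
        | (pd.to_numeric(trials["points"], errors="coerce").fillna(0) > 0)
    )
    if fed_back.any():
        warnings.warn(
            f"{int(fed_back.sum())} test-phase trial(s) carry outcome/points values; "
            "the devaluation tests are run in nominal extinction",
            UserWarning,
            stacklevel=2,
        )


def read_trials(trials_path, subjects_path) -> list[SubjectDataset]:
    """Read a cohort back from the CSV pair written by :func:`write_trials`.

    Round-trips all modelling-relevant fields; schedules are not
    reconstructed (they are implicit in the trial rows).
    """
    trials = pd.read_csv(trials_path)
    subjects = pd.read_csv(subjects_path)
    _validate_trials(trials)
    out = []
    for row in subjects.itertuples(index=False):
        sub_trials = trials[trials["subject"] == row.subject].reset_index(drop=True)
        true_params = {k: getattr(row, k) for k in subjects.columns if k.startswith("true_")}
        out.append(
            SubjectDataset(
                subject=str(row.subject),
                group=str(row.group),
                schedule=None,
                trials=sub_trials,
                binge_count_3mo=int(row.binge_count_3mo),
                vomit_count_3mo=int(row.vomit_count_3mo),
                true_params=true_params,
            )
        )
    return out
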
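"""Reinforcement-learning model of the instrumental learning phase.

A standard delta-rule learner over stimulus x response values,

    V[j, a] <- V[j, a] + alpha * (O - V[j, a]),

where the obtained outcome O is either the points actually awarded (the
reaction-time-dependent variant, 0..5 with faster correct responses earning
more) or a fixed 5 for every correct response.  Choices come from a softmax
adapted with a perseveration term:

    p(left | j, t) = logistic(beta_t * (V[j,left] - V[j,right]) + tau_t * rep)

with rep = +1/-1/0 when the previous response to stimulus j was
left/right/absent.  Exploration (beta) and perseveration (tau) drift
log-linearly over the normalized trial index: beta_t = beta0 *
exp(beta_slope * t/T) and tau_t = tau0 * exp(tau_slope * t/T), allowing both
tendencies to strengthen or fade over the phase.

The model applies to the learning phase only: the later test phases give no
feedback, so there is no outcome signal to drive value updates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task_schedule import N_ITEMS, RESPONSE_WINDOW_MS, TaskSchedule

MAX_POINTS = 5.0
PE_VARIANTS = ("rt_dependent", "fixed")


@dataclass(frozen=True)
class RLParams:
    alpha: float = 0.3
    beta0: float = 5.0
    beta_slope: float = 0.5
    tau0: float = 0.5
    tau_slope: float = 0.0
    pe_variant: str = "rt_dependent"

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0,1], got {self.alpha}")
        if self.beta0 < 0.0:
            raise ValueError(f"beta0 must be >= 0, got {self.beta0}")
        if self.pe_variant not in PE_VARIANTS:
            raise ValueError(f"pe_variant must be one of {PE_VARIANTS}")


@dataclass
class RLState:
    """Per-stimulus action values and the previous response to each stimulus."""

    values: np.ndarray = field(default_factory=lambda: np.zeros((N_ITEMS, 2)))
    last_response: list[str | None] = field(default_factory=lambda: [None] * N_ITEMS)

    def copy(self) -> "RLState":
        return RLState(self.values.copy(), list(self.last_response))


def trial_outcome(correct: bool, rt_ms: float, variant: str = "rt_dependent") -> float:
    """Points awarded for one learning trial.

    Incorrect (or omitted) responses earn 0.  Correct responses earn a fixed
    5, or — in the reaction-time-dependent variant — 5*(1 - rt/2000), so a
    response at the 2-s deadline earns ~0 and an instant one earns 5.
    """
    if rt_ms < 0:
        raise ValueError(f"negative reaction time: {rt_ms}")
    if variant not in PE_VARIANTS:
        raise ValueError(f"unknown outcome variant {variant!r}")
    if not correct:
        return 0.0
    if variant == "fixed":
        return MAX_POINTS
    return MAX_POINTS * (1.0 - min(rt_ms, RESPONSE_WINDOW_MS) / RESPONSE_WINDOW_MS)


def effective_weights(params: RLParams, trial_index: int, n_trials: int) -> tuple[float, float]:
    """(beta_t, tau_t) at 0-based ``trial_index`` of a phase with ``n_trials``."""
    frac = trial_index / n_trials
    return (
        params.beta0 * math.exp(params.beta_slope * frac),
        params.tau0 * math.exp(params.tau_slope * frac),
    )


def rl_update(state: RLState, stimulus: int, response: str, outcome: float, params: RLParams) -> RLState:
    """Delta-rule update of V[stimulus, response]; returns a new state."""
    new = state.copy()
    a = 0 if response == "left" else 1
    v = new.values[stimulus, a]
    new.values[stimulus, a] = v + params.alpha * (outcome - v)
    new.last_response[stimulus] = response
    return new


def choice_probability(
    state: RLState, stimulus: int, trial_index: int, n_trials: int, params: RLParams
) -> float:
    """Probability of a left response under the perseveration softmax."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    beta_t, tau_t = effective_weights(params, trial_index, n_trials)
    prev = state.last_response[stimulus]
    rep = 0.0 if prev is None else (1.0 if prev == "left" else -1.0)
    x = beta_t * (state.values[stimulus, 0] - state.values[stimulus, 1]) + tau_t * rep
    return 1.0 / (1.0 + math.exp(-x))


def simulate_learning(
    schedule: TaskSchedule,
    params: RLParams,
    rng_seed: int,
    rt_model=None,
) -> pd.DataFrame:
    """Simulate an RL agent through the learning phase of ``schedule``.

    Responses are sampled from :func:`choice_probability`; reaction times
    come from ``rt_model`` (default: the synthetic cohort's RT model), with
    choice confidence 2*|p - 0.5| standing in for belief certainty; points
    follow :func:`trial_outcome`.  Deterministic given ``rng_seed``.
    """
    if rt_model is None:
        from .synthetic_data import RTModel

        rt_model = RTModel()
    rng = np.random.default_rng(rng_seed)
    cmap = schedule.contingencies
    trials = schedule.phase_trials("learning")
    n = len(trials)
    state = RLState()
    rows = []
    for idx, t in enumerate(trials):
        s = t.stimulus
        p_left = choice_probability(state, s, idx, n, params)
        response = "left" if rng.random() < p_left else "right"
        certainty = 2.0 * abs(p_left - 0.5)
        rt = rt_model.sample(certainty, rng)
        correct = response == cmap.stimulus_response[s]
        points = trial_outcome(correct, rt, params.pe_variant)
        outcome_id = float(cmap.stimulus_outcome[s]) if correct else np.nan
        state = rl_update(state, s, response, points, params)
        rows.append(
            {
                "phase": "learning",
                "block": t.block,
                "trial": t.trial,
                "stimulus": s,
                "devalued_items": "",
                "trial_devalued": 0,
                "response": response,
                "rt_ms": rt,
                "outcome_id": outcome_id,
                "points": points,
                "correct": int(correct),
            }
        )
    return pd.DataFrame(rows)


def _learning_arrays(data: pd.DataFrame):
    """Extract (stimulus, response index or -1, points) arrays in task order."""
    d = data[data["phase"] == "learning"].sort_values(["block", "trial"], kind="stable")
    if d.empty:
        raise ValueError("no learning-phase trials in data")
    stims = d["stimulus"].to_numpy(dtype=int)
    resp = d["response"].astype(str).to_numpy()
    ridx = np.where(resp == "left", 0, np.where(resp == "right", 1, -1))
    pts = pd.to_numeric(d["points"], errors="coerce").fillna(0.0).to_numpy(dtype=float)
    return stims, ridx, pts


def log_likelihood_learning(data: pd.DataFrame, params: RLParams) -> float:
    """Log-likelihood of observed learning-phase choices.

    Replays the same value-update path as :func:`simulate_learning`.  Trials
    with no registered response contribute no choice term and leave values
    and perseveration state unchanged.
    """
    return _loglik_from_arrays(*_learning_arrays(data), params)


def _loglik_from_arrays(stims, ridx, pts, params: RLParams) -> float:
    """Hot path shared with the fitting loop (arrays extracted once)."""
    n = len(stims)
    alpha = params.alpha
    values = [[0.0, 0.0] for _ in range(N_ITEMS)]
    last: list[float] = [0.0] * N_ITEMS  # +1 left, -1 right, 0 none
    beta0, bs, tau0, ts = params.beta0, params.beta_slope, params.tau0, params.tau_slope
    ll = 0.0
    for i in range(n):
        a = ridx[i]
        if a < 0:
            continue
        s = stims[i]
        frac = i / n
        beta_t = beta0 * math.exp(bs * frac)
        tau_t = tau0 * math.exp(ts * frac)
        x = beta_t * (values[s][0] - values[s][1]) + tau_t * last[s]
        # log p(observed) without overflow
        if a == 0:
            ll += -math.log1p(math.exp(-x)) if x > -30 else x
        else:
            ll += -math.log1p(math.exp(x)) if x < 30 else -x
        v = values[s][a]
        values[s][a] = v + alpha * (pts[i] - v)
        last[s] = 1.0 if a == 0 else -1.0
    return ll
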
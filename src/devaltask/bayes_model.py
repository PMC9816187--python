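"""Bayesian belief-updating model of all four task phases.

The learner tracks, for every stimulus j, categorical beliefs over

* which response is rewarded (``response_belief``: left- vs right-rewarded),
* whether responding at all pays (``go_belief``: go-rewarded vs
  no-go-correct), and
* which of the six outcomes the stimulus yields (``outcome_belief``).

Evidence is categorical, not valued: each observation multiplies the prior
by a two-point likelihood, lam for the hypothesis consistent with the
evidence and (1 - lam) shared equally among the inconsistent ones,

    P'(h) ∝ L(h) P(h),   L(consistent) = lam,

so the single subject parameter lam in (0.5, 1) is the pace of belief
update: lam near 1 revises beliefs almost instantly, lam near 0.5 barely at
all.

Between the learning phase and each devaluation test, beliefs decay toward
uniform by a fixed mixing weight (identical for all subjects).  During the
tests no feedback is given ("nominal extinction"), so beliefs change only at
the instruction screens that open each block.  A baseline-test instruction
devalues two stimuli directly; a slips-of-action instruction devalues two
outcomes, and its force on each stimulus is marginalized through the
learner's outcome beliefs (Bayesian inversion): the more certain the learner
is that a stimulus yields a devalued outcome, the closer the instruction
evidence is to a full-strength no-go update.

Instructions declare the *current* status of each item, so they replace
rather than compound: each block's update is applied relative to the
stimulus's post-decay base belief, a devaluing update when an item enters
the devalued set and a symmetric revaluing one when it leaves.  Choices
follow probability matching with a small fixed lapse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task_schedule import N_ITEMS

GO, NOGO = 0, 1
LEFT, RIGHT = 0, 1
DEFAULT_DECAY = 0.5
DEFAULT_LAPSE = 0.02


@dataclass(frozen=True)
class BayesParams:
    lam: float = 0.85
    lapse: float = DEFAULT_LAPSE

    def __post_init__(self):
        if not 0.0 < self.lam <= 1.0:
            raise ValueError(f"lam must be in (0, 1], got {self.lam}")
        if not 0.0 <= self.lapse <= 0.2:
            raise ValueError(f"lapse must be in [0, 0.2], got {self.lapse}")


@dataclass(frozen=True)
class InstructionEvent:
    """One block-opening instruction screen of a devaluation test."""

    phase: str
    devalued_items: frozenset[int]
    block: int

    def __post_init__(self):
        if self.phase not in ("slips_of_action", "baseline"):
            raise ValueError(f"instructions occur only in the test phases, got {self.phase!r}")
        if len(self.devalued_items) != 2:
            raise ValueError(f"exactly 2 items are devalued per block, got {sorted(self.devalued_items)}")


def _uniform_state() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return (
        np.full((N_ITEMS, 2), 0.5),
        np.full((N_ITEMS, 2), 0.5),
        np.full((N_ITEMS, N_ITEMS), 1.0 / N_ITEMS),
    )


@dataclass
class BeliefState:
    """Per-stimulus categorical beliefs; rows always sum to 1.

    ``response_belief[j]`` = (P(left-rewarded), P(right-rewarded));
    ``go_belief[j]`` = (P(go-rewarded), P(no-go-correct));
    ``outcome_belief[j, o]`` = P(stimulus j yields outcome o).
    ``instruction_factor`` records the go-odds factor currently applied by
    the active instruction screen (1.0 = none), so a new instruction can
    replace rather than compound it.
    """

    response_belief: np.ndarray = field(default_factory=lambda: _uniform_state()[0])
    go_belief: np.ndarray = field(default_factory=lambda: _uniform_state()[1])
    outcome_belief: np.ndarray = field(default_factory=lambda: _uniform_state()[2])
    instruction_factor: np.ndarray = field(default_factory=lambda: np.ones(N_ITEMS))

    def copy(self) -> "BeliefState":
        return BeliefState(
            self.response_belief.copy(),
            self.go_belief.copy(),
            self.outcome_belief.copy(),
            self.instruction_factor.copy(),
        )

    def check_normalized(self, atol: float = 1e-9) -> None:
        for name in ("response_belief", "go_belief", "outcome_belief"):
            arr = getattr(self, name)
            if not np.allclose(arr.sum(axis=-1), 1.0, atol=atol) or (arr < -atol).any():
                raise AssertionError(f"{name} is not a normalized distribution")


def belief_update(prior: np.ndarray, consistent: int, lam: float) -> np.ndarray:
    """One Bayes step: the consistent hypothesis has likelihood ``lam``,
    each inconsistent one shares (1 - lam) equally."""
    prior = np.asarray(prior, dtype=float)
    k = prior.shape[-1]
    if not 0 <= consistent < k:
        raise ValueError(f"hypothesis index {consistent} out of range for {k} hypotheses")
    like = np.full(k, (1.0 - lam) / (k - 1))
    like[consistent] = lam
    post = like * prior
    total = post.sum()
    if total <= 0.0:
        raise ValueError("posterior has zero mass (certain prior contradicted by certain evidence)")
    return post / total


def observe_learning_trial(
    state: BeliefState,
    stimulus: int,
    response: str,
    outcome_id: int | None,
    rewarded: bool,
    params: BayesParams,
) -> BeliefState:
    """Update beliefs after one learning-phase trial.

    A rewarded left press is evidence for the left-rewarded hypothesis; an
    unrewarded one for right-rewarded (and symmetrically).  Rewards also push
    the go-belief toward go-rewarded and, via the revealed outcome, sharpen
    the outcome belief.
    """
    new = state.copy()
    a = LEFT if response == "left" else RIGHT
    consistent = a if rewarded else 1 - a
    new.response_belief[stimulus] = belief_update(state.response_belief[stimulus], consistent, params.lam)
    if rewarded:
        new.go_belief[stimulus] = belief_update(state.go_belief[stimulus], GO, params.lam)
        if outcome_id is not None:
            new.outcome_belief[stimulus] = belief_update(
                state.outcome_belief[stimulus], int(outcome_id), params.lam
            )
    return new


def decay_beliefs(state: BeliefState, weight: float) -> BeliefState:
    """Mix every belief with the uniform distribution: P <- (1-w) P + w U."""
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"decay weight must be in [0,1], got {weight}")
    new = state.copy()
    new.response_belief = (1 - weight) * state.response_belief + weight * 0.5
    new.go_belief = (1 - weight) * state.go_belief + weight * 0.5
    new.outcome_belief = (1 - weight) * state.outcome_belief + weight / N_ITEMS
    new.instruction_factor = np.ones(N_ITEMS)
    return new


def _instruction_odds_factor(d: float, lam: float) -> float:
    """Go-odds likelihood ratio of an instruction for a stimulus with
    probability ``d`` of being linked to a devalued item."""
    l_go = d * (1.0 - lam) + (1.0 - d) * lam
    l_nogo = d * lam + (1.0 - d) * (1.0 - lam)
    return l_go / l_nogo


def apply_instruction(
    state: BeliefState,
    event: InstructionEvent,
    params: BayesParams,
    contingency_beliefs: BeliefState | None = None,
) -> BeliefState:
    """Update go-beliefs from a block-opening instruction screen.

    Baseline test: the two named stimuli receive a full-strength no-go update
    (evidence strength lam) and all others a go update.  Slips-of-action
    test: the devaluation probability of each stimulus is its summed outcome
    belief over the devalued outcomes (taken from ``contingency_beliefs``,
    default the state itself), and the evidence likelihood interpolates
    between lam (certainly devalued) and 1-lam (certainly valued).  Each new
    instruction replaces the previous block's factor, so repeated valuations
    do not compound and a previously devalued item is revalued when it leaves
    the devalued set.
    """
    cb = state if contingency_beliefs is None else contingency_beliefs
    new = state.copy()
    for s in range(N_ITEMS):
        if event.phase == "baseline":
            d = 1.0 if s in event.devalued_items else 0.0
        else:
            d = float(sum(cb.outcome_belief[s, o] for o in event.devalued_items))
        f = _instruction_odds_factor(d, params.lam)
        p = state.go_belief[s, GO]
        odds = (p / (1.0 - p)) * f / state.instruction_factor[s]
        new.go_belief[s, GO] = odds / (1.0 + odds)
        new.go_belief[s, NOGO] = 1.0 - new.go_belief[s, GO]
        new.instruction_factor[s] = f
    return new


def response_probability(
    state: BeliefState, stimulus: int, phase: str, params: BayesParams
) -> tuple[float, float, float]:
    """(p(go-left), p(go-right), p(no-go)) by probability matching with lapse."""
    p_go = (1.0 - params.lapse) * state.go_belief[stimulus, GO] + params.lapse / 2.0
    p_left = state.response_belief[stimulus, LEFT]
    return (p_go * p_left, p_go * (1.0 - p_left), 1.0 - p_go)


def phase2_choice_probability(state: BeliefState, valued_outcome: int, params: BayesParams) -> float:
    """p(left) in the outcome-action test, by Bayesian inversion.

    The learner weighs each stimulus by its believed probability of yielding
    the still-valued outcome and reads off which response that stimulus
    rewards: b_a = sum_j P_j(valued outcome) P_j(a rewarded).
    """
    b_left = float(np.dot(state.outcome_belief[:, valued_outcome], state.response_belief[:, LEFT]))
    b_right = float(np.dot(state.outcome_belief[:, valued_outcome], state.response_belief[:, RIGHT]))
    q = b_left / (b_left + b_right)
    return (1.0 - params.lapse) * q + params.lapse / 2.0


def replay_phase1(trials: pd.DataFrame, params: BayesParams) -> BeliefState:
    """Run the observer over the recorded learning phase, returning the
    end-of-learning beliefs.  Trials without a registered response carry no
    categorical evidence and are skipped."""
    d = trials[trials["phase"] == "learning"].sort_values(["block", "trial"], kind="stable")
    state = BeliefState()
    for row in d.itertuples(index=False):
        if row.response not in ("left", "right"):
            continue
        rewarded = float(row.points) > 0.0 if pd.notna(row.points) else False
        oid = None if pd.isna(row.outcome_id) or row.outcome_id == "" else int(row.outcome_id)
        state = observe_learning_trial(state, int(row.stimulus), row.response, oid, rewarded, params)
    return state


# ---------------------------------------------------------------------------
# Fast incremental likelihood
# ---------------------------------------------------------------------------


def _parse_devalued(cell) -> frozenset[int]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return frozenset()
    return frozenset(int(x) for x in str(cell).split(";"))


class PhaseLikelihood:
    """Pre-parsed trial arrays for repeated likelihood evaluation.

    Parsing a subject's trial table dominates the cost of a single
    likelihood call, so the fitting loop builds this object once and then
    evaluates :meth:`loglik` for many candidate parameter values.  The
    replay arithmetic mirrors the public single-step operations exactly;
    a dedicated test holds the two routes to 1e-10 agreement.
    """

    def __init__(self, trials: pd.DataFrame):
        t = trials
        d = t[t["phase"] == "learning"].sort_values(["block", "trial"], kind="stable")
        self.p1_stim = [int(x) for x in d["stimulus"]]
        self.p1_resp = [0 if r == "left" else (1 if r == "right" else -1) for r in d["response"]]
        pts = pd.to_numeric(d["points"], errors="coerce").fillna(0.0)
        self.p1_rew = [float(p) > 0.0 for p in pts]
        oid = pd.to_numeric(d["outcome_id"], errors="coerce")
        self.p1_out = [-1 if math.isnan(o) else int(o) for o in oid]

        d2 = t[t["phase"] == "outcome_action"].sort_values(["block", "trial"], kind="stable")
        self.p2_valued = [int(v) for v in pd.to_numeric(d2.get("valued_outcome", pd.Series(dtype=float)), errors="coerce").fillna(-1)] if len(d2) else []
        self.p2_resp = [0 if r == "left" else (1 if r == "right" else -1) for r in d2["response"]] if len(d2) else []

        self.tests: dict[str, dict] = {}
        for phase in ("slips_of_action", "baseline"):
            dp = t[t["phase"] == phase].sort_values(["block", "trial"], kind="stable")
            if dp.empty:
                continue
            blocks = sorted(dp["block"].unique())
            devsets = []
            for b in blocks:
                cells = dp.loc[dp["block"] == b, "devalued_items"]
                devsets.append(_parse_devalued(cells.iloc[0]))
            self.tests[phase] = {
                "stim": [int(x) for x in dp["stimulus"]],
                "block_index": [blocks.index(b) for b in dp["block"]],
                "resp": [0 if r == "left" else (1 if r == "right" else 2) for r in dp["response"]],
                "devsets": devsets,
            }

    # -- replay helpers on plain floats (hot path) --

    def _phase1(self, lam: float, lapse: float, want_ll: bool):
        resp_p = [0.5] * N_ITEMS
        go_p = [0.5] * N_ITEMS
        out_p = [[1.0 / N_ITEMS] * N_ITEMS for _ in range(N_ITEMS)]
        inc = (1.0 - lam) / (N_ITEMS - 1)
        ll = 0.0
        for s, a, rew, o in zip(self.p1_stim, self.p1_resp, self.p1_rew, self.p1_out):
            if a < 0:
                continue
            p = resp_p[s]
            if want_ll:
                pl = (1.0 - lapse) * p + lapse / 2.0
                ll += math.log(pl if a == 0 else 1.0 - pl)
            cons_left = (a == 0) == rew
            if cons_left:
                resp_p[s] = lam * p / (lam * p + (1.0 - lam) * (1.0 - p))
            else:
                resp_p[s] = (1.0 - lam) * p / ((1.0 - lam) * p + lam * (1.0 - p))
            if rew:
                g = go_p[s]
                go_p[s] = lam * g / (lam * g + (1.0 - lam) * (1.0 - g))
                if o >= 0:
                    row = out_p[s]
                    tot = 0.0
                    for k in range(N_ITEMS):
                        row[k] *= lam if k == o else inc
                        tot += row[k]
                    for k in range(N_ITEMS):
                        row[k] /= tot
        return resp_p, go_p, out_p, ll

    def _phase2_ll(self, resp_p, out_p, lapse: float) -> float:
        ll = 0.0
        for v, a in zip(self.p2_valued, self.p2_resp):
            if a < 0 or v < 0:
                continue
            b_left = sum(out_p[s][v] * resp_p[s] for s in range(N_ITEMS))
            b_right = sum(out_p[s][v] * (1.0 - resp_p[s]) for s in range(N_ITEMS))
            q = b_left / (b_left + b_right)
            pl = (1.0 - lapse) * q + lapse / 2.0
            ll += math.log(pl if a == 0 else 1.0 - pl)
        return ll

    def _test_ll(self, phase: str, resp_p, go_p, out_p, lam: float, lapse: float, decay: float) -> float:
        spec = self.tests[phase]
        tiny = 1e-12  # keeps odds and choice terms finite when decay -> 0
        rp = [min(max((1.0 - decay) * p + decay * 0.5, tiny), 1.0 - tiny) for p in resp_p]
        gp = [min(max((1.0 - decay) * p + decay * 0.5, tiny), 1.0 - tiny) for p in go_p]
        op = [[(1.0 - decay) * q + decay / N_ITEMS for q in row] for row in out_p]
        base_odds = [g / (1.0 - g) for g in gp]
        # p(go) per stimulus per block, with lapse
        pgo = []
        for devset in spec["devsets"]:
            row = []
            for s in range(N_ITEMS):
                if phase == "baseline":
                    d = 1.0 if s in devset else 0.0
                else:
                    d = sum(op[s][o] for o in devset)
                l_go = d * (1.0 - lam) + (1.0 - d) * lam
                l_ng = d * lam + (1.0 - d) * (1.0 - lam)
                odds = base_odds[s] * (l_go / l_ng)
                g = odds / (1.0 + odds)
                row.append((1.0 - lapse) * g + lapse / 2.0)
            pgo.append(row)
        ll = 0.0
        for s, bi, a in zip(spec["stim"], spec["block_index"], spec["resp"]):
            pg = pgo[bi][s]
            if a == 2:
                ll += math.log(1.0 - pg)
            elif a == 0:
                ll += math.log(pg * rp[s])
            else:
                ll += math.log(pg * (1.0 - rp[s]))
        return ll

    def loglik(
        self,
        lam: float,
        lapse: float = DEFAULT_LAPSE,
        decay_weight: float = DEFAULT_DECAY,
        phases: tuple[str, ...] = ("baseline",),
    ) -> float:
        resp_p, go_p, out_p, ll1 = self._phase1(lam, lapse, want_ll="learning" in phases)
        ll = ll1 if "learning" in phases else 0.0
        if "outcome_action" in phases:
            ll += self._phase2_ll(resp_p, out_p, lapse)
        for phase in ("slips_of_action", "baseline"):
            if phase in phases:
                if phase not in self.tests:
                    raise ValueError(f"no {phase} trials in data")
                ll += self._test_ll(phase, resp_p, go_p, out_p, lam, lapse, decay_weight)
        return ll

    def n_obs(self, phases: tuple[str, ...]) -> int:
        n = 0
        if "learning" in phases:
            n += sum(1 for a in self.p1_resp if a >= 0)
        if "outcome_action" in phases:
            n += sum(1 for a, v in zip(self.p2_resp, self.p2_valued) if a >= 0 and v >= 0)
        for phase in ("slips_of_action", "baseline"):
            if phase in phases and phase in self.tests:
                n += len(self.tests[phase]["stim"])
        return n


def log_likelihood_phase(
    trials: pd.DataFrame,
    phase: str,
    params: BayesParams,
    decay_weight: float = DEFAULT_DECAY,
) -> float:
    """Log-likelihood of the observed choices in one phase.

    The learning phase is always replayed first to supply priors; the two
    devaluation tests each start from the decayed end-of-learning beliefs
    and update only at instruction screens.  Non-responses in the test
    phases are scored as deliberate no-go choices.
    """
    if phase not in ("learning", "outcome_action", "slips_of_action", "baseline"):
        raise ValueError(f"unknown phase {phase!r}")
    if not (trials["phase"] == phase).any():
        raise ValueError(f"no {phase} trials in data")
    return PhaseLikelihood(trials).loglik(
        params.lam, params.lapse, decay_weight, phases=(phase,)
    )
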
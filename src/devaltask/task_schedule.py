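"""Four-phase instrumental learning and devaluation task structure.

The task has six discriminative stimuli (boxes labelled with animal images),
two responses (left / right button press) and six distinct outcomes (animal
images inside the boxes).  Phases:

1. ``learning`` — instrumental learning with feedback: 6 blocks x 12 trials,
   each stimulus twice per block in randomized order.
2. ``outcome_action`` — outcome-action knowledge test: each trial shows one
   left-earned and one right-earned outcome with one crossed out; the correct
   response is the one that earned the still-valued outcome.  Each outcome is
   crossed out exactly twice (12 trials).
3. ``slips_of_action`` — 9 blocks x 12 trials in nominal extinction.  Before
   each block an instruction screen devalues two *outcomes*; responses to
   stimuli linked with devalued outcomes are commission errors.
4. ``baseline`` — identical structure, but two *stimuli* are devalued per
   block.

Tests 3 and 4 are administered in counterbalanced order.  Every devalued item
appears in exactly 3 of the 9 blocks; block devaluation pairs form a
3-regular pair design built from a one-factorization of K6.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

RESPONSES = ("left", "right")
N_ITEMS = 6
PHASES = ("learning", "outcome_action", "slips_of_action", "baseline")
TEST_PHASES = ("slips_of_action", "baseline")
N_TEST_BLOCKS = 9
TRIALS_PER_BLOCK = 12
RESPONSE_WINDOW_MS = 2000.0

# 20 ways of assigning exactly 3 of the 6 stimuli to the left response,
# crossed with the 6 cyclic rotations of the stimulus->outcome bijection.
_LEFT_SETS = list(itertools.combinations(range(N_ITEMS), 3))
N_COUNTERBALANCE = len(_LEFT_SETS) * N_ITEMS  # 120


class ScheduleConfigError(ValueError):
    """Invalid schedule configuration (e.g. out-of-range counterbalance id)."""


@dataclass(frozen=True)
class ContingencyMap:
    """Stimulus->response and stimulus->outcome assignments for one subject."""

    stimulus_response: dict[int, str]
    stimulus_outcome: dict[int, int]
    counterbalance_id: int

    @property
    def outcome_response(self) -> dict[int, str]:
        """Which response earns each outcome."""
        return {o: self.stimulus_response[s] for s, o in self.stimulus_outcome.items()}

    @property
    def outcome_stimulus(self) -> dict[int, int]:
        return {o: s for s, o in self.stimulus_outcome.items()}

    def stimuli_for_response(self, response: str) -> list[int]:
        return [s for s in range(N_ITEMS) if self.stimulus_response[s] == response]


def make_contingencies(counterbalance_id: int) -> ContingencyMap:
    """Build one of the 120 counterbalanced stimulus-response-outcome maps.

    ``counterbalance_id`` indexes (left-response stimulus triple) x (cyclic
    rotation of the stimulus->outcome bijection).
    """
    if not 0 <= counterbalance_id < N_COUNTERBALANCE:
        raise ScheduleConfigError(
            f"counterbalance_id must be in [0, {N_COUNTERBALANCE}), got {counterbalance_id}"
        )
    left = set(_LEFT_SETS[counterbalance_id // N_ITEMS])
    rot = counterbalance_id % N_ITEMS
    return ContingencyMap(
        stimulus_response={s: ("left" if s in left else "right") for s in range(N_ITEMS)},
        stimulus_outcome={s: (s + rot) % N_ITEMS for s in range(N_ITEMS)},
        counterbalance_id=counterbalance_id,
    )


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial.

    ``stimulus`` is set in phases 1, 3 and 4.  In the outcome-action test it
    is ``None`` and ``outcome_pair`` holds (left-earned, right-earned) outcome
    ids with ``crossed_out`` naming the devalued one of the pair.
    ``devalued`` is the block's 2-item devaluation set (outcome ids in the
    slips-of-action test, stimulus ids in the baseline test, empty elsewhere).
    """

    phase: str
    block: int
    trial: int
    stimulus: int | None = None
    outcome_pair: tuple[int, int] | None = None
    crossed_out: int | None = None
    devalued: frozenset[int] = field(default_factory=frozenset)


@dataclass
class TaskSchedule:
    contingencies: ContingencyMap
    trials: list[TrialSpec]
    test_order: str
    seed: int
    n_learning_blocks: int = 6

    def phase_trials(self, phase: str) -> list[TrialSpec]:
        return [t for t in self.trials if t.phase == phase]

    def devalued_sets(self, phase: str) -> list[frozenset[int]]:
        """Per-block devaluation sets for a test phase, in block order."""
        out: dict[int, frozenset[int]] = {}
        for t in self.phase_trials(phase):
            out[t.block] = t.devalued
        return [out[b] for b in sorted(out)]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            pair = t.outcome_pair
            rows.append(
                {
                    "phase": t.phase,
                    "block": t.block,
                    "trial": t.trial,
                    "stimulus": "" if t.stimulus is None else t.stimulus,
                    "outcome_left": "" if pair is None else pair[0],
                    "outcome_right": "" if pair is None else pair[1],
                    "crossed_out_outcome": "" if t.crossed_out is None else t.crossed_out,
                    "devalued_items": ";".join(str(i) for i in sorted(t.devalued)),
                }
            )
        return pd.DataFrame(rows)

    def config_dict(self) -> dict:
        return {
            "seed": int(self.seed),
            "test_order": self.test_order,
            "n_learning_blocks": int(self.n_learning_blocks),
            "counterbalance_id": int(self.contingencies.counterbalance_id),
            "stimulus_response": {int(k): v for k, v in self.contingencies.stimulus_response.items()},
            "stimulus_outcome": {int(k): int(v) for k, v in self.contingencies.stimulus_outcome.items()},
        }

    def save(self, trials_path, config_path) -> None:
        self.to_frame().to_csv(trials_path, index=False)
        with open(config_path, "w") as fh:
            if str(config_path).endswith(".json"):
                json.dump(self.config_dict(), fh, indent=1)
            else:
                yaml.safe_dump(self.config_dict(), fh)


def _devaluation_pairs(rng: np.random.Generator) -> list[frozenset[int]]:
    """9 unordered 2-item devaluation sets, each item in exactly 3 of them.

    Three of the five perfect matchings of the round-robin one-factorization
    of K6 are drawn; their 9 edges give each item degree 3.  Block order is
    then shuffled.
    """
    factors = []
    for k in range(5):
        pairs = [frozenset({5, k})]
        for i in (1, 2):
            pairs.append(frozenset({(k + i) % 5, (k - i) % 5}))
        factors.append(pairs)
    chosen = rng.choice(5, size=3, replace=False)
    pairs = [p for k in chosen for p in factors[k]]
    rng.shuffle(pairs)
    return pairs


def _block_stimulus_order(rng: np.random.Generator) -> list[int]:
    order = list(range(N_ITEMS)) * 2
    rng.shuffle(order)
    return order


def generate_schedule(
    seed: int,
    counterbalance_id: int = 0,
    test_order: str = "slips_first",
    n_learning_blocks: int = 6,
) -> TaskSchedule:
    """Generate a complete, reproducible four-phase schedule.

    Identical arguments always produce an identical schedule.  ``test_order``
    chooses which devaluation test comes first ("slips_first" or
    "baseline_first").
    """
    if test_order not in ("slips_first", "baseline_first"):
        raise ScheduleConfigError(f"unknown test_order {test_order!r}")
    if n_learning_blocks < 1:
        raise ScheduleConfigError("n_learning_blocks must be >= 1")
    cmap = make_contingencies(counterbalance_id)
    rng = np.random.default_rng(seed)
    trials: list[TrialSpec] = []

    for block in range(1, n_learning_blocks + 1):
        for i, stim in enumerate(_block_stimulus_order(rng), start=1):
            trials.append(TrialSpec("learning", block, i, stimulus=stim))

    # Outcome-action test: two rounds, each outcome crossed out once per
    # round, paired with a random outcome earned by the other response.
    oa: list[TrialSpec] = []
    by_resp = {r: [cmap.stimulus_outcome[s] for s in cmap.stimuli_for_response(r)] for r in RESPONSES}
    pairs = []
    for _ in range(2):
        for crossed in range(N_ITEMS):
            resp = cmap.outcome_response[crossed]
            other = RESPONSES[1 - RESPONSES.index(resp)]
            partner = int(rng.choice(by_resp[other]))
            left_o, right_o = (crossed, partner) if resp == "left" else (partner, crossed)
            pairs.append((left_o, right_o, crossed))
    rng.shuffle(pairs)
    for i, (lo, ro, crossed) in enumerate(pairs, start=1):
        oa.append(TrialSpec("outcome_action", 1, i, outcome_pair=(lo, ro), crossed_out=crossed))
    trials.extend(oa)

    def test_phase(phase: str) -> list[TrialSpec]:
        out = []
        for block, devset in enumerate(_devaluation_pairs(rng), start=1):
            for i, stim in enumerate(_block_stimulus_order(rng), start=1):
                out.append(TrialSpec(phase, block, i, stimulus=stim, devalued=devset))
        return out

    order = ("slips_of_action", "baseline") if test_order == "slips_first" else ("baseline", "slips_of_action")
    for phase in order:
        trials.extend(test_phase(phase))

    return TaskSchedule(cmap, trials, test_order, seed, n_learning_blocks)


def validate_schedule(schedule: TaskSchedule) -> list[str]:
    """Check every structural invariant; return human-readable violations."""
    v: list[str] = []
    cmap = schedule.contingencies
    if sorted(cmap.stimulus_outcome) != list(range(N_ITEMS)):
        v.append("contingencies: stimulus set is not 0..5")
    if sorted(cmap.stimulus_outcome.values()) != list(range(N_ITEMS)):
        v.append("contingencies: stimulus->outcome is not a bijection onto 0..5")
    for r in RESPONSES:
        n = len(cmap.stimuli_for_response(r))
        if n != 3:
            v.append(f"contingencies: {n} stimuli mapped to response {r!r}, expected 3")

    learn = schedule.phase_trials("learning")
    blocks = sorted({t.block for t in learn})
    if blocks != list(range(1, schedule.n_learning_blocks + 1)):
        v.append(f"learning: block ids {blocks} != 1..{schedule.n_learning_blocks}")
    for b in blocks:
        stims = [t.stimulus for t in learn if t.block == b]
        if len(stims) != TRIALS_PER_BLOCK:
            v.append(f"learning block {b}: {len(stims)} trials, expected {TRIALS_PER_BLOCK}")
        for s in range(N_ITEMS):
            if stims.count(s) != 2:
                v.append(f"learning block {b}: stimulus {s} appears {stims.count(s)}x, expected 2")

    oa = schedule.phase_trials("outcome_action")
    crossed = [t.crossed_out for t in oa]
    for o in range(N_ITEMS):
        if crossed.count(o) != 2:
            v.append(f"outcome_action: outcome {o} crossed out {crossed.count(o)}x, expected 2")
    for t in oa:
        if t.outcome_pair is None or t.crossed_out not in t.outcome_pair:
            v.append(f"outcome_action trial {t.trial}: crossed-out outcome not in shown pair")
        elif cmap.outcome_response[t.outcome_pair[0]] != "left" or cmap.outcome_response[t.outcome_pair[1]] != "right":
            v.append(f"outcome_action trial {t.trial}: pair is not (left-earned, right-earned)")

    for phase in TEST_PHASES:
        tt = schedule.phase_trials(phase)
        blocks = sorted({t.block for t in tt})
        if blocks != list(range(1, N_TEST_BLOCKS + 1)):
            v.append(f"{phase}: block ids {blocks} != 1..{N_TEST_BLOCKS}")
        counts: dict[int, int] = {i: 0 for i in range(N_ITEMS)}
        for b in blocks:
            bt = [t for t in tt if t.block == b]
            devsets = {t.devalued for t in bt}
            if len(devsets) != 1:
                v.append(f"{phase} block {b}: inconsistent devalued sets within block")
            dev = next(iter(devsets))
            if len(dev) != 2:
                v.append(f"{phase} block {b}: devalued set has {len(dev)} items, expected 2")
            for i in dev:
                counts[i] = counts.get(i, 0) + 1
            stims = [t.stimulus for t in bt]
            if len(stims) != TRIALS_PER_BLOCK:
                v.append(f"{phase} block {b}: {len(stims)} trials, expected {TRIALS_PER_BLOCK}")
            for s in range(N_ITEMS):
                if stims.count(s) != 2:
                    v.append(f"{phase} block {b}: stimulus {s} appears {stims.count(s)}x, expected 2")
        for i in range(N_ITEMS):
            if counts.get(i, 0) != 3:
                v.append(f"{phase}: item {i} devalued in {counts.get(i, 0)} blocks, expected 3")
    for phase in ("learning", "slips_of_action", "baseline"):
        for t in schedule.phase_trials(phase):
            if phase == "learning" and t.devalued:
                v.append(f"learning block {t.block} trial {t.trial}: non-empty devalued set")
    return v


def score_contingency_knowledge(answers: dict, truth: ContingencyMap, kind: str) -> int:
    """Score a post-task contingency questionnaire; 6 = perfect knowledge.

    ``kind`` is "S-R" (stimulus->response), "S-O" (stimulus->outcome) or
    "R-O" (outcome->earning response).  ``answers`` must cover all 6 items.
    """
    if kind == "S-R":
        key = truth.stimulus_response
    elif kind == "S-O":
        key = truth.stimulus_outcome
    elif kind == "R-O":
        key = truth.outcome_response
    else:
        raise ValueError(f"unknown contingency kind {kind!r}")
    missing = set(key) - set(answers)
    if missing:
        raise ValueError(f"incomplete answer sheet for {kind}: missing items {sorted(missing)}")
    return sum(1 for item, correct in key.items() if answers[item] == correct)
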
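import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from devaltask import BayesParams, BeliefState, InstructionEvent, bayes_model as bm


def test_single_step_posteriors():
    uniform = np.array([0.5, 0.5])
    assert np.allclose(bm.belief_update(uniform, 0, 0.5), uniform)
    assert np.allclose(bm.belief_update(uniform, 0, 0.8), [0.8, 0.2])
    # certainty overrides a strong contrary prior
    assert np.allclose(bm.belief_update(np.array([0.99, 0.01]), 1, 1.0), [0.0, 1.0])
    # 6-way: consistent outcome gets lam, the rest share (1-lam)/5
    post = bm.belief_update(np.full(6, 1 / 6), 2, 0.7)
    assert post[2] == pytest.approx(0.7) and np.allclose(np.delete(post, 2), 0.06)
    with pytest.raises(ValueError, match="out of range"):
        bm.belief_update(uniform, 5, 0.8)


@given(p=st.floats(0.05, 0.95), lam=st.floats(0.55, 0.95))
def test_two_consistent_updates_compose_to_squared_odds(p, lam):
    prior = np.array([p, 1.0 - p])
    twice = bm.belief_update(bm.belief_update(prior, 0, lam), 0, lam)
    odds = (p / (1.0 - p)) * (lam / (1.0 - lam)) ** 2
    assert twice[0] == pytest.approx(odds / (1.0 + odds), rel=1e-9)


@given(p=st.floats(0.05, 0.95), lam=st.floats(0.55, 0.9), bump=st.floats(0.01, 0.09))
def test_larger_lam_shifts_posterior_more(p, lam, bump):
    prior = np.array([p, 1.0 - p])
    assert bm.belief_update(prior, 0, lam + bump)[0] > bm.belief_update(prior, 0, lam)[0]


def test_learning_trial_observation():
    params = BayesParams(lam=0.8)
    state = BeliefState()
    rewarded = bm.observe_learning_trial(state, 0, "left", 3, True, params)
    assert rewarded.response_belief[0, 0] == pytest.approx(0.8)
    assert rewarded.go_belief[0, 0] > 0.5
    assert np.argmax(rewarded.outcome_belief[0]) == 3
    unrewarded = bm.observe_learning_trial(state, 0, "left", None, False, params)
    assert unrewarded.response_belief[0, 0] == pytest.approx(0.2)
    # lam = 0.5 is a fixed point for the binary hypothesis sets: the
    # two-point likelihood (0.5, 0.5) carries no information
    still = bm.observe_learning_trial(state, 0, "left", 3, True, BayesParams(lam=0.5))
    assert np.allclose(still.response_belief, state.response_belief)
    assert np.allclose(still.go_belief, state.go_belief)


def test_decay_mixes_toward_uniform():
    state = BeliefState()
    state.response_belief[0] = [0.9, 0.1]
    assert np.allclose(bm.decay_beliefs(state, 0.0).response_belief[0], [0.9, 0.1])
    assert np.allclose(bm.decay_beliefs(state, 1.0).response_belief[0], [0.5, 0.5])
    assert np.allclose(bm.decay_beliefs(state, 0.5).response_belief[0], [0.7, 0.3])
    with pytest.raises(ValueError):
        bm.decay_beliefs(state, 1.5)


def test_instruction_updates_baseline_and_inversion():
    params = BayesParams(lam=0.9)
    state = BeliefState()
    event = InstructionEvent("baseline", frozenset({0, 1}), 1)
    out = bm.apply_instruction(state, event, params)
    assert out.go_belief[0, bm.NOGO] == pytest.approx(0.9)
    assert out.go_belief[5, bm.GO] == pytest.approx(0.9)

    # certain outcome knowledge makes outcome devaluation as strong as direct
    certain = BeliefState()
    certain.outcome_belief[2] = np.eye(6)[4]
    slips = bm.apply_instruction(certain, InstructionEvent("slips_of_action", frozenset({4, 5}), 1), params)
    assert slips.go_belief[2, bm.NOGO] == pytest.approx(0.9)

    # uncertainty damps the update strictly below the certain case
    fuzzy = bm.apply_instruction(BeliefState(), InstructionEvent("slips_of_action", frozenset({4, 5}), 1), params)
    assert fuzzy.go_belief[2, bm.NOGO] < slips.go_belief[2, bm.NOGO]


def test_new_instruction_replaces_rather_than_compounds():
    """An item leaving the devalued set is revalued back to its base-level
    go belief; repeated valued blocks do not pile up evidence."""
    params = BayesParams(lam=0.8)
    state = BeliefState()
    state.go_belief[:] = [0.7, 0.3]
    b1 = bm.apply_instruction(state, InstructionEvent("baseline", frozenset({0, 1}), 1), params)
    b2 = bm.apply_instruction(b1, InstructionEvent("baseline", frozenset({2, 3}), 2), params)
    b3 = bm.apply_instruction(b2, InstructionEvent("baseline", frozenset({4, 5}), 3), params)
    # stimulus 0: devalued in block 1, valued thereafter -> same as any valued stimulus
    assert b2.go_belief[0, bm.GO] == pytest.approx(b3.go_belief[1, bm.GO], rel=1e-9)
    # valued stimuli keep one go update relative to base, regardless of block count
    assert b3.go_belief[1, bm.GO] == pytest.approx(b1.go_belief[2, bm.GO], rel=1e-9)


def test_response_probability_product_rule():
    params = BayesParams(lam=0.8, lapse=0.0)
    state = BeliefState()
    assert bm.response_probability(state, 0, "baseline", params) == pytest.approx((0.25, 0.25, 0.5))
    state.go_belief[1] = [0.0, 1.0]
    assert bm.response_probability(state, 1, "baseline", params)[:2] == pytest.approx((0.0, 0.0))
    state.go_belief[2] = [0.8, 0.2]
    state.response_belief[2] = [0.9, 0.1]
    assert bm.response_probability(state, 2, "baseline", params) == pytest.approx((0.72, 0.08, 0.2))


@given(
    lam=st.floats(0.55, 0.99),
    moves=st.lists(st.tuples(st.integers(0, 5), st.booleans(), st.booleans()), max_size=15),
)
def test_beliefs_remain_normalized_through_any_trajectory(lam, moves):
    params = BayesParams(lam=lam)
    state = BeliefState()
    for stim, left, rewarded in moves:
        state = bm.observe_learning_trial(state, stim, "left" if left else "right",
                                          stim if rewarded else None, rewarded, params)
        state.check_normalized()
    state = bm.decay_beliefs(state, 0.5)
    state = bm.apply_instruction(state, InstructionEvent("slips_of_action", frozenset({0, 3}), 1), params)
    state.check_normalized()


def test_single_uninformed_test_trial_scores_log_half():
    trials = pd.DataFrame(
        {
            "phase": ["baseline"],
            "block": [1],
            "trial": [1],
            "stimulus": [2],
            "devalued_items": ["0;1"],
            "response": ["none"],
            "rt_ms": [np.nan],
            "outcome_id": [np.nan],
            "points": [np.nan],
        }
    )
    ll = bm.log_likelihood_phase(trials, "baseline", BayesParams(lam=0.5, lapse=0.0))
    assert ll == pytest.approx(math.log(0.5), abs=1e-12)
    with pytest.raises(ValueError, match="no slips_of_action trials"):
        bm.log_likelihood_phase(trials, "slips_of_action", BayesParams(lam=0.8))


def test_phase_likelihood_equals_stepwise_replay(bayes_trials):
    """Dual-route check: the incremental likelihood must agree with a naive
    replay through the public single-step operations to 1e-10."""
    params = BayesParams(lam=0.77)
    for phase in ("learning", "outcome_action", "slips_of_action", "baseline"):
        fast = bm.log_likelihood_phase(bayes_trials, phase, params)
        slow = _stepwise_loglik(bayes_trials, phase, params)
        assert fast == pytest.approx(slow, abs=1e-10)


def _stepwise_loglik(trials, phase, params, decay=0.5):
    if phase == "learning":
        state = BeliefState()
        ll = 0.0
        for row in trials[trials.phase == "learning"].sort_values(["block", "trial"]).itertuples():
            p = (1 - params.lapse) * state.response_belief[int(row.stimulus), 0] + params.lapse / 2
            ll += math.log(p if row.response == "left" else 1 - p)
            oid = None if pd.isna(row.outcome_id) else int(row.outcome_id)
            state = bm.observe_learning_trial(state, int(row.stimulus), row.response, oid,
                                              float(row.points) > 0, params)
        return ll
    state = bm.replay_phase1(trials, params)
    ll = 0.0
    if phase == "outcome_action":
        for row in trials[trials.phase == "outcome_action"].sort_values(["block", "trial"]).itertuples():
            p = bm.phase2_choice_probability(state, int(row.valued_outcome), params)
            ll += math.log(p if row.response == "left" else 1 - p)
        return ll
    state = bm.decay_beliefs(state, decay)
    current = None
    for row in trials[trials.phase == phase].sort_values(["block", "trial"]).itertuples():
        dev = frozenset(int(x) for x in str(row.devalued_items).split(";"))
        if row.block != current:
            state = bm.apply_instruction(state, InstructionEvent(phase, dev, row.block), params)
            current = row.block
        pgl, pgr, png = bm.response_probability(state, int(row.stimulus), phase, params)
        ll += math.log({"left": pgl, "right": pgr, "none": png}[row.response])
    return ll


def test_likelihood_prefers_generating_lam(schedule):
    from devaltask import synthetic_data

    diffs = []
    for seed in range(50):
        trials = synthetic_data.simulate_bayes_subject(schedule, lam=0.9, rng_seed=seed)
        like = bm.PhaseLikelihood(trials)
        phases = ("learning", "outcome_action", "slips_of_action", "baseline")
        diffs.append(like.loglik(0.9, phases=phases) - like.loglik(0.65, phases=phases))
    assert np.mean(diffs) > 0.0
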
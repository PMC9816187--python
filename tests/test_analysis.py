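import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from devaltask import analysis
from devaltask import synthetic_data as sd


def _frame(rows):
    return pd.DataFrame(rows)


def test_accuracy_by_block_flags_degenerate_blocks():
    rows = []
    for t in range(1, 4):
        rows.append({"subject": "s", "phase": "learning", "block": 1, "trial": t,
                     "response": "left", "correct": 1})
    for t in range(1, 4):
        rows.append({"subject": "s", "phase": "learning", "block": 2, "trial": t,
                     "response": "none", "correct": 0})
    acc = analysis.accuracy_by_block(_frame(rows))
    b1 = acc[acc.block == 1].iloc[0]
    b2 = acc[acc.block == 2].iloc[0]
    assert b1.accuracy == 1.0 and not b1.all_omitted
    assert np.isnan(b2.accuracy) and b2.all_omitted and b2.n_omitted == 3


def test_learning_trend_on_simulated_learners(small_cohort):
    trials, _ = sd.cohort_frames(small_cohort)
    acc = analysis.accuracy_by_block(trials)
    mean_by_block = acc.groupby("block")["accuracy"].mean()
    assert mean_by_block.iloc[-1] > mean_by_block.iloc[0]
    # Spearman trend over blocks is positive
    assert stats.spearmanr(mean_by_block.index, mean_by_block.values).statistic > 0


def _dsi_frame(n_dev_resp, n_dev, n_val_resp, n_val):
    rows = []
    t = 0
    for i in range(n_dev):
        t += 1
        rows.append({"subject": "s", "phase": "baseline", "block": 1, "trial": t,
                     "trial_devalued": 1, "response": "left" if i < n_dev_resp else "none"})
    for i in range(n_val):
        t += 1
        rows.append({"subject": "s", "phase": "baseline", "block": 1, "trial": t,
                     "trial_devalued": 0, "response": "right" if i < n_val_resp else "none"})
    return _frame(rows)


def test_dsi_formula():
    assert analysis.compute_dsi(_dsi_frame(0, 3, 3, 3), "baseline")["dsi"].iloc[0] == 100.0
    assert analysis.compute_dsi(_dsi_frame(3, 3, 3, 3), "baseline")["dsi"].iloc[0] == 0.0
    # respond to 1/3 of devalued and all valued trials -> DSI = 100 - 33.3
    val = analysis.compute_dsi(_dsi_frame(1, 3, 3, 3), "baseline")["dsi"].iloc[0]
    assert val == pytest.approx(100 * 2 / 3)
    with pytest.raises(ValueError):
        analysis.compute_dsi(_dsi_frame(1, 3, 3, 3), "learning")


def test_dsi_invariant_to_order_and_duplication():
    base = _dsi_frame(2, 6, 5, 6)
    shuffled = base.sample(frac=1.0, random_state=0)
    doubled = pd.concat([base, base], ignore_index=True)
    v0 = analysis.compute_dsi(base, "baseline")["dsi"].iloc[0]
    assert analysis.compute_dsi(shuffled, "baseline")["dsi"].iloc[0] == pytest.approx(v0)
    assert analysis.compute_dsi(doubled, "baseline")["dsi"].iloc[0] == pytest.approx(v0)


def test_identical_groups_give_null_interaction(small_cohort):
    trials, _ = sd.cohort_frames(small_cohort)
    hc = trials[trials.group == "HC"]
    mirrored = hc.copy()
    mirrored["group"] = "BN"
    mirrored["subject"] = mirrored["subject"] + "_bn"
    res = analysis.group_valuation_test(pd.concat([hc, mirrored], ignore_index=True), "baseline")
    assert abs(res.estimate) < 1e-6
    assert 0.0 <= res.p_value <= 1.0


def test_interaction_requires_two_groups(small_cohort):
    trials, _ = sd.cohort_frames(small_cohort)
    solo = trials[trials.subject.isin(["hc001", "bn001"])]
    with pytest.raises(ValueError, match="two groups"):
        analysis.group_valuation_test(solo, "baseline")


def test_collapsed_test_requires_both_tests(small_cohort):
    trials, _ = sd.cohort_frames(small_cohort)
    res = analysis.collapsed_valuation_test(trials)
    assert 0.0 <= res.p_value <= 1.0
    with pytest.raises(ValueError, match="missing baseline"):
        analysis.collapsed_valuation_test(trials[trials.phase != "baseline"])


def test_rank_sum_matches_exhaustive_enumeration():
    """3-vs-3 fixture: the Mann-Whitney statistic and exact p-value are
    validated against direct enumeration of all 20 rank assignments."""
    hc, bn = [1.0, 4.0, 6.0], [2.0, 3.0, 5.0]
    df = pd.DataFrame({"subject": list("abcdef"), "group": ["HC"] * 3 + ["BN"] * 3,
                       "lam": hc + bn})
    res = analysis.compare_parameter(df, "lam")
    u_brute = sum(x > y for x in hc for y in bn) + 0.5 * sum(x == y for x in hc for y in bn)
    assert res.statistic == u_brute
    pooled = hc + bn
    ranks_u = []
    for combo in itertools.combinations(range(6), 3):
        grp1 = [pooled[i] for i in combo]
        grp2 = [pooled[i] for i in range(6) if i not in combo]
        ranks_u.append(sum(x > y for x in grp1 for y in grp2))
    observed = ranks_u[0]  # first combination is the actual assignment (0,1,2)
    extreme = sum(1 for u in ranks_u if abs(u - 4.5) >= abs(observed - 4.5)) / len(ranks_u)
    assert res.p_value == pytest.approx(extreme)
    assert res.extras["rank_biserial"] == pytest.approx(1 - 2 * u_brute / 9)


def test_rank_sum_handles_pure_ties():
    df = pd.DataFrame({"subject": list("abcdef"), "group": ["HC"] * 3 + ["BN"] * 3,
                       "lam": [0.7] * 6})
    res = analysis.compare_parameter(df, "lam")
    assert res.p_value == 1.0 and res.extras["ties_only"]


def test_rank_sum_power_under_shift():
    rng = np.random.default_rng(8)
    rejections = 0
    for _ in range(100):
        hc = rng.normal(0.0, 1.0, 30)
        bn = rng.normal(-1.0, 1.0, 30)
        df = pd.DataFrame({"subject": range(60), "group": ["HC"] * 30 + ["BN"] * 30,
                           "v": np.concatenate([hc, bn])})
        rejections += analysis.compare_parameter(df, "v").p_value < 0.05
    assert rejections > 90


def test_symptom_regression_contract():
    link = sd.SymptomLink()
    rng = np.random.default_rng(3)
    lams = rng.uniform(0.55, 0.95, 60)
    counts = [link.sample(l, rng)[0] for l in lams]
    res = analysis.symptom_regression(counts, lams, name="lam")
    assert res.estimate < 0 and 0 <= res.p_value <= 1
    const = analysis.symptom_regression(counts, np.full(60, 0.7))
    assert np.isnan(const.estimate) and "degenerate" in const.extras
    with pytest.raises(ValueError, match="zero"):
        analysis.symptom_regression(np.zeros(10), lams[:10])


def test_symptom_regression_null_calibration():
    link = sd.SymptomLink()
    rng = np.random.default_rng(17)
    rejections = 0
    n_rep = 40
    for _ in range(n_rep):
        lams = rng.uniform(0.55, 0.95, 60)
        counts = np.array([link.sample(l, rng)[0] for l in lams])
        permuted = rng.permutation(lams)
        rejections += analysis.symptom_regression(counts, permuted).p_value < 0.05
    assert rejections / n_rep <= 0.15


def test_rt_regression_robustness_and_null():
    rng = np.random.default_rng(6)
    lams = rng.uniform(0.55, 0.95, 40)
    noise_rts = rng.normal(700, 30, 40)
    null = analysis.rt_update_regression(noise_rts, lams)
    assert abs(null.estimate) < 200.0 and null.p_value > 0.01
    # a single extreme outlier: Huber stays closer to the clean OLS slope
    clean_rts = 700 - 400 * (lams - 0.75) + rng.normal(0, 20, 40)
    import statsmodels.api as sm

    clean_slope = sm.OLS(clean_rts, sm.add_constant(lams)).fit().params[1]
    dirty = clean_rts.copy()
    dirty[0] = 10_000.0
    ols_dirty = sm.OLS(dirty, sm.add_constant(lams)).fit().params[1]
    huber_dirty = analysis.rt_update_regression(dirty, lams).estimate
    assert abs(huber_dirty - clean_slope) < abs(ols_dirty - clean_slope)
    with pytest.raises(ValueError, match="3 subjects"):
        analysis.rt_update_regression([700.0, 650.0], [0.7, 0.8])
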
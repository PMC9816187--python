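"""Behavioral and statistical layer: accuracy curves, devaluation
sensitivity, group x valuation mixed models, parameter group comparisons,
symptom regressions and the reaction-time cross-check.

Devaluation sensitivity index (DSI): percent of valued trials responded to
minus percent of devalued trials responded to, computed over all scheduled
trials (an omission counts as no response, since the tests score
withholding).  Higher DSI = more flexible, goal-directed adjustment.

The group x valuation test fits a linear mixed model of response percentages
(per subject x valuation x test half) on group, valuation and their
interaction with a subject random intercept; the reported contract is the
interaction estimate, statistic and p-value, plus valued-only and
devalued-only rank-sum contrasts.  Solvers are standard library routines
(statsmodels MixedLM / NegativeBinomial / RLM, scipy rank tests); the
quantities and contrast structure are defined here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

TEST_PHASES = ("slips_of_action", "baseline")


@dataclass(frozen=True)
class DevaluationSummary:
    subject: str
    test: str
    pct_valued: float
    pct_devalued: float

    @property
    def dsi(self) -> float:
        return self.pct_valued - self.pct_devalued


@dataclass(frozen=True)
class GroupTestResult:
    effect_name: str
    estimate: float
    standard_error: float
    statistic: float
    p_value: float
    n_obs: int
    extras: dict = field(default_factory=dict)


def accuracy_by_block(trials: pd.DataFrame, phase: str = "learning") -> pd.DataFrame:
    """Per-subject, per-block accuracy among registered responses.

    Blocks with no registered response get accuracy NaN and are flagged in
    the ``all_omitted`` column; omissions are counted separately.
    """
    d = trials[trials["phase"] == phase]
    if d.empty:
        raise ValueError(f"no {phase} trials")
    responded = d["response"].isin(["left", "right"])
    g = d.assign(responded=responded, hit=d["correct"].astype(float) * responded)
    out = (
        g.groupby(["subject", "block"], as_index=False)
        .agg(n_trials=("trial", "size"), n_responses=("responded", "sum"), n_correct=("hit", "sum"))
    )
    out["n_omitted"] = out["n_trials"] - out["n_responses"]
    with np.errstate(invalid="ignore"):
        out["accuracy"] = np.where(out["n_responses"] > 0, out["n_correct"] / out["n_responses"], np.nan)
    out["all_omitted"] = out["n_responses"] == 0
    return out


def compute_dsi(trials: pd.DataFrame, test: str) -> pd.DataFrame:
    """Per-subject devaluation summary for one test phase.

    A "response" is any registered press within the window; percentages are
    over all scheduled valued (resp. devalued) trials.
    """
    if test not in TEST_PHASES:
        raise ValueError(f"test must be one of {TEST_PHASES}, got {test!r}")
    d = trials[trials["phase"] == test]
    if d.empty:
        raise ValueError(f"no {test} trials")
    responded = d["response"].isin(["left", "right"]).astype(float)
    g = d.assign(responded=responded)
    rows = []
    for subject, sub in g.groupby("subject"):
        dev = sub["trial_devalued"].astype(int) == 1
        rows.append(
            {
                "subject": subject,
                "test": test,
                "pct_valued": 100.0 * sub.loc[~dev, "responded"].mean(),
                "pct_devalued": 100.0 * sub.loc[dev, "responded"].mean(),
            }
        )
    out = pd.DataFrame(rows)
    out["dsi"] = out["pct_valued"] - out["pct_devalued"]
    return out


def _response_percent_long(trials: pd.DataFrame, tests: tuple[str, ...], n_splits: int = 2) -> pd.DataFrame:
    """Long table of response percentages per subject x test x valuation x
    sub-unit (test halves by default), for the mixed models."""
    d = trials[trials["phase"].isin(tests)].copy()
    if d.empty:
        raise ValueError(f"no trials in phases {tests}")
    d["responded"] = d["response"].isin(["left", "right"]).astype(float)
    rows = []
    for (subject, group, phase), sub in d.groupby(["subject", "group", "phase"]):
        blocks = sorted(sub["block"].unique())
        splits = np.array_split(np.array(blocks), n_splits)
        for half, blk in enumerate(splits, start=1):
            part = sub[sub["block"].isin(blk)]
            for valuation, mask in (("valued", part["trial_devalued"] == 0), ("devalued", part["trial_devalued"] == 1)):
                sel = part[mask]
                if len(sel):
                    rows.append(
                        {"subject": subject, "group": group, "test": phase, "half": half,
                         "valuation": valuation, "pct_responses": 100.0 * sel["responded"].mean()}
                    )
    return pd.DataFrame(rows)


def _interaction_mixed_model(long: pd.DataFrame, effect_name: str) -> GroupTestResult:
    long = long.copy()
    long["is_bn"] = (long["group"] == "BN").astype(float)
    long["is_dev"] = (long["valuation"] == "devalued").astype(float)
    long["inter"] = long["is_bn"] * long["is_dev"]
    groups = long.groupby("group")["subject"].nunique()
    if (groups < 2).any() or len(groups) < 2:
        raise ValueError("need two groups with at least 2 subjects each")
    exog = sm.add_constant(long[["is_bn", "is_dev", "inter"]])
    # random intercept plus a random valuation slope: subjects differ in how
    # strongly devaluation suppresses their responding, and ignoring that
    # heterogeneity makes the interaction test anticonservative
    exog_re = sm.add_constant(long[["is_dev"]])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(long["pct_responses"], exog, groups=long["subject"], exog_re=exog_re)
        res = None
        for method in ("bfgs", "lbfgs", "powell", "nm"):
            try:
                res = model.fit(reml=True, method=method)
                break
            except np.linalg.LinAlgError:
                continue
        if res is None:
            raise RuntimeError("mixed model failed to converge with all optimizers")
    est = float(res.params["inter"])
    se = float(res.bse["inter"])
    stat = float(res.tvalues["inter"])
    p = float(res.pvalues["inter"])
    # post-hoc group contrasts within each valuation level (rank-sum)
    extras = {}
    per_subj = long.groupby(["subject", "group", "valuation"], as_index=False)["pct_responses"].mean()
    for valuation in ("valued", "devalued"):
        sub = per_subj[per_subj["valuation"] == valuation]
        hc = sub.loc[sub["group"] == "HC", "pct_responses"]
        bn = sub.loc[sub["group"] == "BN", "pct_responses"]
        w = stats.mannwhitneyu(hc, bn, alternative="two-sided")
        extras[f"{valuation}_contrast_p"] = float(w.pvalue)
        extras[f"{valuation}_contrast_W"] = float(w.statistic)
    return GroupTestResult(effect_name, est, se, stat, p, int(len(long)), extras)


def group_valuation_test(trials: pd.DataFrame, test: str, n_splits: int = 2) -> GroupTestResult:
    """Group x valuation interaction on percent responses for one test."""
    long = _response_percent_long(trials, (test,), n_splits)
    return _interaction_mixed_model(long, f"group x valuation ({test})")


def collapsed_valuation_test(trials: pd.DataFrame, n_splits: int = 2) -> GroupTestResult:
    """Group x valuation interaction with both tests folded into one pool."""
    for test in TEST_PHASES:
        if not (trials["phase"] == test).any():
            raise ValueError(f"collapsed analysis requires both tests; missing {test}")
    long = _response_percent_long(trials, TEST_PHASES, n_splits)
    return _interaction_mixed_model(long, "group x valuation (collapsed)")


def compare_parameter(values: pd.DataFrame, parameter: str) -> GroupTestResult:
    """Wilcoxon rank-sum comparison of a per-subject value between groups.

    ``values`` needs columns subject, group and ``parameter``.  Reports the
    Mann-Whitney W of the HC group, group medians and the rank-biserial
    effect size; ties are handled by the normal approximation with tie
    correction and flagged in ``extras``.
    """
    hc = values.loc[values["group"] == "HC", parameter].to_numpy(dtype=float)
    bn = values.loc[values["group"] == "BN", parameter].to_numpy(dtype=float)
    if len(hc) == 0 or len(bn) == 0:
        raise ValueError("both groups must be present")
    all_ties = len(np.unique(np.concatenate([hc, bn]))) == 1
    method = "asymptotic" if all_ties else "auto"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.mannwhitneyu(hc, bn, alternative="two-sided", method=method)
    u = float(res.statistic)
    rank_biserial = 1.0 - 2.0 * u / (len(hc) * len(bn))
    return GroupTestResult(
        f"group difference in {parameter}",
        estimate=float(np.median(hc) - np.median(bn)),
        standard_error=float("nan"),
        statistic=u,
        p_value=1.0 if all_ties else float(res.pvalue),
        n_obs=len(hc) + len(bn),
        extras={
            "median_HC": float(np.median(hc)),
            "median_BN": float(np.median(bn)),
            "rank_biserial": rank_biserial,
            "ties_only": all_ties,
        },
    )


def symptom_regression(counts, predictor, name: str = "predictor") -> GroupTestResult:
    """Negative-binomial (log link) regression of a symptom count on one
    per-subject predictor (DSI or lambda)."""
    counts = np.asarray(counts, dtype=float)
    predictor = np.asarray(predictor, dtype=float)
    if np.all(counts == 0):
        raise ValueError("all symptom counts are zero; NB fit is degenerate")
    if np.ptp(predictor) == 0:
        return GroupTestResult(
            f"NB slope on {name}", float("nan"), float("nan"), float("nan"), float("nan"),
            len(counts), {"degenerate": "constant predictor"},
        )
    exog = sm.add_constant(predictor)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.NegativeBinomial(counts, exog).fit(disp=0, maxiter=200)
    return GroupTestResult(
        f"NB slope on {name}",
        estimate=float(res.params[1]),
        standard_error=float(res.bse[1]),
        statistic=float(res.tvalues[1]),
        p_value=float(res.pvalues[1]),
        n_obs=len(counts),
        extras={"alpha": float(res.params[-1])},
    )


def rt_update_regression(rts, lambdas) -> GroupTestResult:
    """Huber robust regression of mean valued-trial RT on fitted lambda.

    On default synthetic cohorts the slope is negative: slower updaters
    (smaller lambda) respond more slowly on valuable trials.
    """
    rts = np.asarray(rts, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    keep = np.isfinite(rts) & np.isfinite(lambdas)
    if keep.sum() < 3:
        raise ValueError("need at least 3 subjects with RT and lambda")
    exog = sm.add_constant(lambdas[keep])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.RLM(rts[keep], exog, M=sm.robust.norms.HuberT()).fit()
    z = float(res.params[1] / res.bse[1])
    return GroupTestResult(
        "Huber slope of valued-trial RT on lambda",
        estimate=float(res.params[1]),
        standard_error=float(res.bse[1]),
        statistic=z,
        p_value=float(2.0 * stats.norm.sf(abs(z))),
        n_obs=int(keep.sum()),
    )


def mean_valued_rt(trials: pd.DataFrame, test: str) -> pd.DataFrame:
    """Per-subject mean RT on valued trials with a registered response."""
    d = trials[(trials["phase"] == test) & (trials["trial_devalued"] == 0)]
    d = d[d["response"].isin(["left", "right"])]
    out = d.groupby("subject", as_index=False)["rt_ms"].mean()
    return out.rename(columns={"rt_ms": "mean_valued_rt_ms"})
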
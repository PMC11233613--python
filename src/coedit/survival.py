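"""Survival screening of co-editing pairs and group-comparison statistics.

Cox proportional-hazards fits use the partial likelihood with Efron tie
handling (via lifelines). A prognostic "risk pair" must show a significant
adverse pair effect (p < 0.05, HR > 1) at three stages: univariate,
adjusted for the two single-site editing indicators, and additionally
adjusted for age, gender, stage, grade and AFP (complete-case).
Patients carrying at least one risk pair form the high-risk group.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.base import BaseEstimator

from .datatypes import ClinicalTable, EditingMatrix
from .stats import bh_adjust, fisher_exact_2x2, ranksum_test

log = logging.getLogger(__name__)

__all__ = [
    "CoxFit",
    "RiskAssignment",
    "fit_cox",
    "PairSurvivalScreen",
    "logrank_test",
    "assign_risk_groups",
    "categorical_group_test",
    "feature_group_comparison",
    "km_curve",
]


@dataclass
class CoxFit:
    coef: pd.Series  # log hazard ratios
    hr: pd.Series
    se: pd.Series
    p: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    log_likelihood: float
    n: int
    n_events: int
    penalized: bool = False


@dataclass
class RiskAssignment:
    patient_id: str
    n_risk_pairs: int
    group: str  # 'high' | 'low'


def fit_cox(df: pd.DataFrame, duration_col: str = "os_time",
            event_col: str = "os_event", penalizer: float = 0.0) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties, Newton optimization).

    ``df`` holds the durations, events and every covariate column to use.
    Constant covariates raise; monotone-likelihood/separation problems are
    retried with a small ridge penalty and flagged.
    """
    covs = [c for c in df.columns if c not in (duration_col, event_col)]
    if df[event_col].sum() < 2:
        raise ValueError("need at least 2 events")
    for c in covs:
        if df[c].nunique() <= 1:
            raise ValueError(f"constant covariate: {c}")
    penalized = penalizer > 0
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=duration_col, event_col=event_col)
        if (not np.isfinite(cph.summary["se(coef)"]).all()
                or (np.abs(cph.params_) > 10).any()
                or (cph.summary["se(coef)"] > 10).any()):
            raise ValueError("diverged coefficients")
    except Exception:  # noqa: BLE001 - convergence / separation fallback
        if penalizer > 0:
            raise
        return fit_cox(df, duration_col, event_col, penalizer=0.1)
    s = cph.summary
    return CoxFit(
        coef=s["coef"], hr=s["exp(coef)"], se=s["se(coef)"], p=s["p"],
        ci_lower=s["coef lower 95%"], ci_upper=s["coef upper 95%"],
        log_likelihood=float(cph.log_likelihood_),
        n=len(df), n_events=int(df[event_col].sum()), penalized=penalized,
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """k-group log-rank test; returns (chi-square statistic, p)."""
    groups = pd.Series(list(groups))
    if groups.nunique() < 2:
        raise ValueError("log-rank needs at least 2 groups")
    res = multivariate_logrank_test(pd.Series(list(times)), groups, pd.Series(list(events)))
    return float(res.test_statistic), float(res.p_value)


class PairSurvivalScreen(BaseEstimator):
    """Three-stage Cox screen of co-editing pairs for prognostic value.

    ``fit(pairs, edit, clinical)`` evaluates each (site_i, site_j) pair:

    stage 1 — univariate Cox on the co-edited indicator;
    stage 2 — Cox with the co-edited indicator plus both single-site edited
        indicators (adjusting away effects carried by one site alone);
    stage 3 — stage 2 plus age, gender, stage, grade and AFP
        (complete-case).

    ``risk_pairs_`` lists pairs with p < ``p_threshold`` and HR > 1 at all
    three stages; ``results_`` holds per-pair statistics including a
    three-group (co-edited / single-edited / non-edited) log-rank test.
    """

    CLINICAL_COVS = ("age", "gender", "stage", "grade", "afp")

    def __init__(self, p_threshold: float = 0.05, use_fdr: bool = False):
        self.p_threshold = p_threshold
        self.use_fdr = use_fdr

    def fit(self, pairs, edit: EditingMatrix, clinical: ClinicalTable):
        patients = [p for p in clinical.patient_ids if p in edit.status.columns]
        clin = clinical.data.loc[patients]
        rows = []
        for si, sj in pairs:
            xi = edit.status.loc[si, patients].to_numpy(int)
            xj = edit.status.loc[sj, patients].to_numpy(int)
            both = xi & xj
            row = {"site_i": si, "site_j": sj,
                   "n_coedited": int(both.sum()), "skip_reason": ""}
            base = pd.DataFrame({
                "os_time": clin["os_time"].to_numpy(float),
                "os_event": clin["os_event"].to_numpy(int),
                "pair": both,
            }, index=patients)
            if both.sum() == 0 or both.sum() == len(both):
                row["skip_reason"] = "pair indicator constant"
                rows.append(row)
                continue
            if base.loc[base["pair"] == 1, "os_event"].sum() == 0 or \
               base.loc[base["pair"] == 0, "os_event"].sum() == 0:
                row["skip_reason"] = "a group has zero events"
                rows.append(row)
                continue
            try:
                f1 = fit_cox(base)
                row["uni_coef"], row["uni_hr"], row["uni_p"] = (
                    float(f1.coef["pair"]), float(f1.hr["pair"]), float(f1.p["pair"]))
            except ValueError as e:
                row["skip_reason"] = f"stage1: {e}"
                rows.append(row)
                continue

            m2 = base.copy()
            m2["site_i_edit"], m2["site_j_edit"] = xi, xj
            # the pair indicator must not duplicate a single-site column
            if np.array_equal(both, xi) or np.array_equal(both, xj):
                row["skip_reason"] = "pair indicator identical to a single site"
                rows.append(row)
                continue
            try:
                f2 = fit_cox(m2)
                row["adj_site_coef"], row["adj_site_hr"], row["adj_site_p"] = (
                    float(f2.coef["pair"]), float(f2.hr["pair"]), float(f2.p["pair"]))
            except ValueError as e:
                row["skip_reason"] = f"stage2: {e}"
                rows.append(row)
                continue

            m3 = m2.copy()
            m3["age"] = clin["age"].to_numpy(float)
            m3["gender"] = (clin["gender"] == "male").astype(float).to_numpy()
            m3["stage"] = clin["stage"].to_numpy(float)
            m3["grade"] = clin["grade"].to_numpy(float)
            m3["afp"] = np.log1p(clin["afp"].to_numpy(float))
            m3 = m3.dropna()
            row["n_stage3"] = len(m3)
            try:
                f3 = fit_cox(m3)
                row["adj_clin_coef"], row["adj_clin_hr"], row["adj_clin_p"] = (
                    float(f3.coef["pair"]), float(f3.hr["pair"]), float(f3.p["pair"]))
            except ValueError as e:
                row["skip_reason"] = f"stage3: {e}"
                rows.append(row)
                continue

            tri = np.where(both == 1, "co-edited",
                           np.where((xi | xj) == 1, "single-edited", "non-edited"))
            if len(np.unique(tri)) >= 2:
                row["logrank_stat"], row["logrank_p"] = logrank_test(
                    base["os_time"], base["os_event"], tri)
            rows.append(row)

        results = pd.DataFrame(rows)
        self.results_ = results
        ok = results["skip_reason"] == "" if len(results) else pd.Series(dtype=bool)
        stage_cols = ["uni_p", "adj_site_p", "adj_clin_p"]
        hr_cols = ["uni_hr", "adj_site_hr", "adj_clin_hr"]
        if len(results) and ok.any() and all(c in results for c in stage_cols):
            cand = results[ok].copy()
            if self.use_fdr:
                for c in stage_cols:
                    cand[c] = bh_adjust(cand[c])
            sig = np.ones(len(cand), dtype=bool)
            for pc, hc in zip(stage_cols, hr_cols):
                sig &= (cand[pc] < self.p_threshold).to_numpy()
                sig &= (cand[hc] > 1).to_numpy()
            self.risk_pairs_ = [
                (r.site_i, r.site_j) for r in cand[sig].itertuples()
            ]
        else:
            self.risk_pairs_ = []
        return self


def assign_risk_groups(edit: EditingMatrix, risk_pairs, patients=None) -> list[RiskAssignment]:
    """Count risk pairs carried (both sites edited) per patient.

    A patient is high-risk iff they carry at least one risk pair.
    Deterministic and idempotent.
    """
    if patients is None:
        patients = edit.sample_ids
    out = []
    for p in patients:
        n = 0
        for si, sj in risk_pairs:
            if edit.status.loc[si, p] == 1 and edit.status.loc[sj, p] == 1:
                n += 1
        out.append(RiskAssignment(patient_id=p, n_risk_pairs=n,
                                  group="high" if n >= 1 else "low"))
    return out


def categorical_group_test(group_labels, category_labels) -> tuple[float, float]:
    """Two-sided Fisher's exact test of a binary grouping against a binary
    category (e.g. high/low risk vs stage 1-2 / 3-4). Missing categories
    are excluded; degenerate tables return (nan, 1.0)."""
    g = pd.Series(list(group_labels))
    c = pd.Series(list(category_labels))
    ok = g.notna() & c.notna()
    g, c = g[ok], c[ok]
    gl, cl = sorted(g.unique()), sorted(c.unique())
    if len(gl) != 2 or len(cl) != 2:
        return float("nan"), 1.0
    table = [[int(((g == gi) & (c == ci)).sum()) for ci in cl] for gi in gl]
    return fisher_exact_2x2(table)


def feature_group_comparison(
    features: pd.DataFrame, groups: pd.Series, alternative: str = "two-sided"
) -> pd.DataFrame:
    """Per-feature rank-sum comparison between two groups with BH.

    ``features`` is samples x features; ``groups`` maps sample -> label
    (exactly two labels). Direction is the sign of the median difference
    (first label minus second, labels sorted); constant features get p = 1
    and a flag.
    """
    groups = groups.reindex(features.index).dropna()
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {labels}")
    ia = groups.index[groups == labels[0]]
    ib = groups.index[groups == labels[1]]
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("need >= 2 observations per group")
    rows = []
    for feat in features.columns:
        a = features.loc[ia, feat].dropna().to_numpy(float)
        b = features.loc[ib, feat].dropna().to_numpy(float)
        pooled = np.concatenate([a, b])
        if np.unique(pooled).size <= 1:
            rows.append({"feature": feat, "p": 1.0, "direction": "none",
                         "constant": True})
            continue
        p = ranksum_test(a, b, alternative=alternative)
        diff = float(np.median(a) - np.median(b))
        rows.append({
            "feature": feat, "p": p,
            "direction": "none" if diff == 0 else ("up" if diff > 0 else "down"),
            "constant": False,
        })
    df = pd.DataFrame(rows)
    df["fdr"] = bh_adjust(df["p"])
    return df


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan–Meier survival-curve coordinates (for CSV export/plotting)."""
    km = KaplanMeierFitter()
    km.fit(list(times), event_observed=list(events))
    sf = km.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(float),
                         "survival": sf.iloc[:, 0].to_numpy(float)})
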
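"""Per-site editing statistics.

Editing-associated genes: for a given editing site, genes whose expression
differs between edited and non-edited tumor samples (rank-sum test, BH,
FDR < 0.05, at least 2-fold change in either direction), optionally
confirmed by a logistic screen adjusting for clinical confounders.

Site classification: tumor-gain / tumor-loss sites (Fisher's exact test on
editing frequency tumor vs normal plus a < 5% frequency requirement in the
other group) and dysregulated-editing sites (paired t-test on editing
levels in matched tumor/normal pairs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .datatypes import ClinicalTable, EditingMatrix, ExpressionBundle
from .stats import bh_adjust, fisher_exact_2x2

log = logging.getLogger(__name__)

__all__ = [
    "AssociationRecord",
    "SiteClassification",
    "EditingAssociationScreen",
    "editing_associated_genes",
    "adjust_confounders",
    "classify_sites",
    "correlate_levels_expression",
]

FC_PSEUDOCOUNT = 0.01  # added to both group means; FPKM zeros are common


@dataclass
class AssociationRecord:
    site_id: str
    gene_id: str
    wilcoxon_p: float
    fdr: float
    fold_change: float  # mean(edited) / mean(non-edited)
    direction: str  # 'up' | 'down'
    adjusted_pass: bool | None = None
    separation_flag: bool = False


@dataclass
class SiteClassification:
    site_id: str
    site_class: str  # 'hcc_gain' | 'hcc_loss' | 'dys_edit' | 'none'
    fisher_p: float = np.nan
    fisher_fdr: float = np.nan
    paired_p: float = np.nan
    paired_fdr: float = np.nan
    max_level_change: float = np.nan
    n_supporting_pairs: int = 0


def _site_associations(
    edit: EditingMatrix,
    expr: ExpressionBundle,
    site_id: str,
    min_group: int,
    fdr_threshold: float,
    fold_threshold: float,
) -> list[AssociationRecord] | None:
    """Rank-sum screen of every gene for one site; None if site ineligible."""
    tumor = [s for s in expr.tumor_samples() if s in edit.status.columns]
    status = edit.status.loc[site_id, tumor]
    edited = status.index[status == 1]
    non_edited = status.index[status == 0]
    if len(edited) < min_group or len(non_edited) < min_group:
        return None
    vals = expr.values[tumor]
    a = vals[edited].to_numpy()
    b = vals[non_edited].to_numpy()
    # vectorized rank-sum across genes; scipy picks exact for small tie-free
    # groups and the mid-rank normal approximation otherwise
    method = "auto" if max(len(edited), len(non_edited)) <= 8 else "asymptotic"
    with np.errstate(all="ignore"):
        res = sps.mannwhitneyu(a, b, axis=1, alternative="two-sided", method=method)
    pvals = np.asarray(res.pvalue, dtype=float)
    fc = (a.mean(axis=1) + FC_PSEUDOCOUNT) / (b.mean(axis=1) + FC_PSEUDOCOUNT)
    fdr = bh_adjust(pvals)
    keep = (fdr < fdr_threshold) & ((fc > fold_threshold) | (fc < 1.0 / fold_threshold))
    records = []
    for gi in np.nonzero(keep)[0]:
        records.append(
            AssociationRecord(
                site_id=site_id,
                gene_id=expr.gene_ids[gi],
                wilcoxon_p=float(pvals[gi]),
                fdr=float(fdr[gi]),
                fold_change=float(fc[gi]),
                direction="up" if fc[gi] > 1 else "down",
            )
        )
    return records


def editing_associated_genes(
    edit: EditingMatrix,
    expr: ExpressionBundle,
    site_id: str,
    min_group: int = 3,
    fdr_threshold: float = 0.05,
    fold_threshold: float = 2.0,
) -> list[AssociationRecord]:
    """Candidate editing-associated genes for one site (tumor samples only).

    Two-sided rank-sum test per gene between edited and non-edited tumor
    samples, BH across genes, kept at FDR < 0.05 with > 2-fold change in
    either direction. Sites with fewer than ``min_group`` samples on either
    side are skipped (empty list, reason logged).
    """
    recs = _site_associations(edit, expr, site_id, min_group, fdr_threshold, fold_threshold)
    if recs is None:
        log.info("site %s skipped: fewer than %d samples in a group", site_id, min_group)
        return []
    return recs


COVARIATES = ("age", "gender", "bmi", "stage", "grade")


def adjust_confounders(
    records: list[AssociationRecord],
    edit: EditingMatrix,
    expr: ExpressionBundle,
    clinical: ClinicalTable,
    fdr_threshold: float = 0.05,
) -> list[AssociationRecord]:
    """Logistic confounder adjustment of candidate associations.

    Per record, fits editing status (outcome) on log2 expression plus age,
    gender, BMI, stage and grade over complete-case tumor samples; BH across
    the candidate set on the expression coefficient; sets ``adjusted_pass``.
    Perfect separation falls back to a small ridge penalty and flags the
    record.
    """
    if not records:
        return records
    tumor = [s for s in expr.tumor_samples() if s in edit.status.columns]
    cov = clinical.data.reindex(tumor)[list(COVARIATES)].copy()
    cov["gender"] = (cov["gender"] == "male").astype(float)
    usable_cov = [c for c in COVARIATES if not cov[c].isna().all()]
    dropped = set(COVARIATES) - set(usable_cov)
    if dropped:
        log.warning("covariates dropped (all missing): %s", sorted(dropped))
    complete = cov[usable_cov].dropna().index
    pvals = np.empty(len(records))
    flags = np.zeros(len(records), dtype=bool)
    for i, rec in enumerate(records):
        y = edit.status.loc[rec.site_id, complete].to_numpy(float)
        x_expr = np.log2(expr.values.loc[rec.gene_id, complete].to_numpy(float) + 1.0)
        X = sm.add_constant(
            np.column_stack([x_expr, cov.loc[complete, usable_cov].to_numpy(float)])
        )
        p, flagged = _logit_expr_pvalue(y, X)
        pvals[i] = p
        flags[i] = flagged
    fdr = bh_adjust(pvals)
    for rec, p, q, fl in zip(records, pvals, fdr, flags):
        rec.adjusted_pass = bool(q < fdr_threshold)
        rec.separation_flag = bool(fl)
    return records


def _logit_expr_pvalue(y: np.ndarray, X: np.ndarray) -> tuple[float, bool]:
    """Wald p for the expression coefficient (column 1); ridge on separation."""
    import warnings

    if y.min() == y.max():
        return 1.0, True
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if np.isfinite(fit.bse[1]) and fit.mle_retvals.get("converged", False):
            return float(fit.pvalues[1]), False
    except Exception:  # noqa: BLE001 - PerfectSeparation & numeric failures
        pass
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.Logit(y, X).fit_regularized(disp=0, alpha=1.0, L1_wt=0.0, maxiter=500)
        se = np.sqrt(np.diag(np.linalg.pinv(-sm.Logit(y, X).hessian(fit.params))))
    z = fit.params[1] / se[1] if se[1] > 0 else 0.0
    return float(2 * sps.norm.sf(abs(z))), True


class EditingAssociationScreen(BaseEstimator):
    """Editing-associated-gene screen across all eligible sites.

    scikit-learn style estimator: ``fit(edit, expr[, clinical])`` runs the
    rank-sum screen per site (and, when a clinical table is supplied, the
    logistic confounder adjustment), leaving the results in
    ``records_`` (flat list) and ``by_site_`` (site -> records that passed
    every applied filter).

    Parameters
    ----------
    min_group : minimum edited and non-edited tumor samples per site.
    fdr : BH threshold for the rank-sum screen (and the adjusted screen).
    fold_change : fold-change threshold, applied in both directions.
    adjust : whether to run the confounder-adjusted screen when clinical
        data is available.
    """

    def __init__(self, min_group: int = 3, fdr: float = 0.05,
                 fold_change: float = 2.0, adjust: bool = True):
        self.min_group = min_group
        self.fdr = fdr
        self.fold_change = fold_change
        self.adjust = adjust

    def fit(self, edit: EditingMatrix, expr: ExpressionBundle,
            clinical: ClinicalTable | None = None):
        records: list[AssociationRecord] = []
        skipped = []
        for site in edit.site_ids:
            recs = _site_associations(
                edit, expr, site, self.min_group, self.fdr, self.fold_change
            )
            if recs is None:
                skipped.append(site)
                continue
            records.extend(recs)
        if self.adjust and clinical is not None and records:
            records = adjust_confounders(records, edit, expr, clinical, self.fdr)
        self.records_ = records
        self.skipped_sites_ = skipped
        by_site: dict[str, list[AssociationRecord]] = {}
        for rec in records:
            if rec.adjusted_pass is False:
                continue
            by_site.setdefault(rec.site_id, []).append(rec)
        self.by_site_ = by_site
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records_])


def classify_sites(
    edit_tumor: pd.DataFrame,
    edit_normal: pd.DataFrame,
    paired_levels: tuple[pd.DataFrame, pd.DataFrame] | None = None,
    gain_loss_fdr: float = 0.05,
    low_freq: float = 0.05,
    dys_fdr: float = 0.2,
    dys_p: float = 0.01,
    dys_delta: float = 0.25,
    dys_min_pairs: int = 2,
) -> list[SiteClassification]:
    """Classify sites as tumor-gain, tumor-loss, dys-edit or none.

    Gain/loss: two-sided Fisher's exact test on edited counts tumor vs
    normal (BH, FDR < 0.05) with editing frequency < 5% in normal (gain) or
    tumor (loss). Dys-edit: paired t-test on matched tumor/normal editing
    levels (BH; FDR < 0.2 and p < 0.01) with |level change| > 0.25 in at
    least 2 pairs. Gain/loss takes precedence when both apply.
    """
    sites = list(edit_tumor.index)
    nt, nn = edit_tumor.shape[1], edit_normal.shape[1]
    fisher_p = np.empty(len(sites))
    for i, s in enumerate(sites):
        kt = int(edit_tumor.loc[s].sum())
        kn = int(edit_normal.loc[s].sum())
        _, fisher_p[i] = fisher_exact_2x2([[kt, nt - kt], [kn, nn - kn]])
    fisher_fdr = bh_adjust(fisher_p)

    paired_stats = {}
    if paired_levels is not None:
        lt, ln = paired_levels
        t_p, deltas_all = {}, {}
        for s in sites:
            if s not in lt.index or s not in ln.index:
                continue
            both = lt.loc[s].notna() & ln.loc[s].notna()
            if both.sum() < 2:
                continue
            d = (lt.loc[s, both] - ln.loc[s, both]).to_numpy(float)
            if np.allclose(d.std(), 0):
                p = 0.0 if np.abs(d).max() > 0 else 1.0
            else:
                p = float(sps.ttest_rel(lt.loc[s, both], ln.loc[s, both]).pvalue)
            t_p[s] = p
            deltas_all[s] = d
        if t_p:
            keys = list(t_p)
            fdrs = bh_adjust([t_p[k] for k in keys])
            for k, q in zip(keys, fdrs):
                d = deltas_all[k]
                paired_stats[k] = (t_p[k], float(q), float(np.abs(d).max()),
                                   int((np.abs(d) > dys_delta).sum()))

    out = []
    for i, s in enumerate(sites):
        freq_t = edit_tumor.loc[s].mean()
        freq_n = edit_normal.loc[s].mean()
        cls = "none"
        rec = SiteClassification(site_id=s, site_class=cls,
                                 fisher_p=float(fisher_p[i]), fisher_fdr=float(fisher_fdr[i]))
        if fisher_fdr[i] < gain_loss_fdr:
            if freq_n < low_freq and freq_t > freq_n:
                rec.site_class = "hcc_gain"
            elif freq_t < low_freq and freq_n > freq_t:
                rec.site_class = "hcc_loss"
        if rec.site_class == "none" and s in paired_stats:
            p, q, mx, npairs = paired_stats[s]
            rec.paired_p, rec.paired_fdr = p, q
            rec.max_level_change, rec.n_supporting_pairs = mx, npairs
            if q < dys_fdr and p < dys_p and npairs >= dys_min_pairs:
                rec.site_class = "dys_edit"
        out.append(rec)
    return out


def correlate_levels_expression(
    edit: EditingMatrix,
    expr: ExpressionBundle,
    gene_subset: list[str] | None = None,
    min_edit_frac: float = 0.25,
    min_obs: int = 3,
) -> pd.DataFrame:
    """Pearson correlation of editing level vs host-gene expression.

    Sites are restricted to those edited in at least ``min_edit_frac`` of
    tumor samples (and to ``gene_subset`` host genes when given); the
    correlation uses edited samples only. BH across tested sites.
    """
    if edit.levels is None:
        raise ValueError("editing levels layer required")
    tumor = [s for s in expr.tumor_samples() if s in edit.status.columns]
    rows = []
    for site in edit.site_ids:
        gene = edit.annotations.loc[site, "gene"] if edit.annotations is not None else None
        if gene_subset is not None and gene not in gene_subset:
            continue
        if gene is None or gene not in expr.values.index:
            continue
        status = edit.status.loc[site, tumor]
        if status.mean() < min_edit_frac:
            continue
        edited = status.index[status == 1]
        lv = edit.levels.loc[site, edited].astype(float)
        ex = expr.values.loc[gene, edited].astype(float)
        ok = lv.notna() & ex.notna()
        if ok.sum() < min_obs:
            continue
        if lv[ok].std() == 0 or ex[ok].std() == 0:
            continue
        r, p = sps.pearsonr(lv[ok], ex[ok])
        rows.append({"site_id": site, "gene_id": gene, "n": int(ok.sum()),
                     "pearson_r": float(r), "p": float(p)})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_adjust(df["p"])
    return df
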
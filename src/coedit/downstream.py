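"""Downstream comparisons.

Differential expression is a deliberately simple, documented procedure:
median-of-ratios size-factor normalization (the DESeq-style geometric-mean
reference) followed by a two-sided rank-sum test per gene and BH
correction, thresholded at FDR < 0.05 and |log2 fold change| > 1. The
claims made downstream (thresholding, direction-consistent intersection,
signature construction) are structural and do not depend on a particular
count model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator
from sklearn.linear_model import LogisticRegression

from .datatypes import CopyNumberSegments, GeneSetCollection
from .stats import bh_adjust, hypergeom_upper_tail, roc_curve_points, trapezoid_auc

log = logging.getLogger(__name__)

__all__ = [
    "DEResult",
    "RankSumDE",
    "differential_expression",
    "shared_dysregulated_intersection",
    "pathway_enrichment",
    "coediting_associated_genes",
    "SignatureModel",
    "call_amplifications",
    "coamplification_test",
    "size_factors",
]


# ------------------------------------------------------------ DE stand-in


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes with all-positive counts.

    Falls back to total-count scaling (with a warning) if no gene has
    positive counts in every sample.
    """
    arr = counts.to_numpy(float)
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        warnings.warn("no gene with all-positive counts; using total-count scaling",
                      stacklevel=2)
        totals = arr.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(totals)))
        return pd.Series(sf, index=counts.columns)
    la = np.log(arr[allpos])
    ref = la.mean(axis=1)  # log geometric mean per gene
    sf = np.exp(np.median(la - ref[:, None], axis=0))
    return pd.Series(sf, index=counts.columns)


@dataclass
class DEResult:
    gene_id: str
    log2_fc: float
    p: float
    fdr: float
    status: str  # 'up' | 'down' | 'ns'


class RankSumDE(BaseEstimator):
    """Rank-sum differential expression with median-of-ratios normalization.

    ``fit(counts, group_a, group_b)`` compares sample lists A vs B;
    ``results_`` has one row per gene with log2 fold change (A over B,
    pseudocount 1), rank-sum p, BH FDR and status.
    """

    def __init__(self, fdr: float = 0.05, lfc_threshold: float = 1.0):
        self.fdr = fdr
        self.lfc_threshold = lfc_threshold

    def fit(self, counts: pd.DataFrame, group_a: list, group_b: list):
        if len(group_a) < 3 or len(group_b) < 3:
            raise ValueError("need >= 3 samples per group")
        sub = counts[list(group_a) + list(group_b)]
        sf = size_factors(sub)
        norm = sub / sf
        a = norm[list(group_a)].to_numpy(float)
        b = norm[list(group_b)].to_numpy(float)
        lfc = np.log2(a.mean(axis=1) + 1.0) - np.log2(b.mean(axis=1) + 1.0)
        with np.errstate(all="ignore"):
            res = sps.mannwhitneyu(a, b, axis=1, alternative="two-sided",
                                   method="asymptotic")
        p = np.asarray(res.pvalue, dtype=float)
        constant = np.array([np.unique(np.concatenate([x, y])).size <= 1
                             for x, y in zip(a, b)])
        p[constant] = 1.0
        q = bh_adjust(p)
        status = np.where(
            (q < self.fdr) & (lfc > self.lfc_threshold), "up",
            np.where((q < self.fdr) & (lfc < -self.lfc_threshold), "down", "ns"),
        )
        self.results_ = pd.DataFrame({
            "gene_id": counts.index, "log2_fc": lfc, "p": p, "fdr": q,
            "status": status,
        }).set_index("gene_id", drop=False)
        self.size_factors_ = sf
        return self

    def up_genes(self) -> set:
        return set(self.results_.index[self.results_["status"] == "up"])

    def down_genes(self) -> set:
        return set(self.results_.index[self.results_["status"] == "down"])


def differential_expression(counts: pd.DataFrame, group_a, group_b,
                            fdr: float = 0.05, lfc_threshold: float = 1.0) -> pd.DataFrame:
    """Functional wrapper over :class:`RankSumDE`."""
    return RankSumDE(fdr=fdr, lfc_threshold=lfc_threshold).fit(counts, group_a, group_b).results_


def shared_dysregulated_intersection(de_a: pd.DataFrame, de_b: pd.DataFrame) -> dict:
    """Direction-consistent intersection of two DE tables.

    Returns {'up': genes up in both, 'down': genes down in both,
    'all': union of the two}.
    """
    up = set(de_a.index[de_a["status"] == "up"]) & set(de_b.index[de_b["status"] == "up"])
    down = set(de_a.index[de_a["status"] == "down"]) & set(de_b.index[de_b["status"] == "down"])
    return {"up": up, "down": down, "all": up | down}


# ------------------------------------------------------------ enrichment


def pathway_enrichment(gene_set, collection: GeneSetCollection, universe,
                       fdr_threshold: float = 0.05) -> pd.DataFrame:
    """Hypergeometric enrichment of ``gene_set`` in each collection set.

    Sets are intersected with the universe first; query genes outside the
    universe are dropped. BH across sets; ``enriched`` flags FDR < 0.05.
    """
    universe = set(universe)
    query = set(gene_set) & universe
    rows = []
    for name, members in collection:
        m = members & universe
        if not m:
            log.info("set %s skipped: empty intersection with universe", name)
            continue
        overlap = len(query & m)
        p = hypergeom_upper_tail(overlap, len(query), len(m), len(universe))
        rows.append({"set": name, "set_size": len(m), "overlap": overlap, "p": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_adjust(df["p"])
        df["enriched"] = df["fdr"] < fdr_threshold
        df = df.sort_values("p", kind="mergesort").reset_index(drop=True)
    return df


def coediting_associated_genes(risk_pairs, assoc_by_site: dict,
                               shared_de_genes: set | None = None,
                               min_pairs: int = 3) -> list[str]:
    """Genes shared (direction-consistently) by >= ``min_pairs`` risk pairs.

    Per risk pair, the co-editing-associated genes are the direction-
    consistent intersection of the two sites' associated genes; genes
    appearing in at least ``min_pairs`` of those per-pair sets — and in the
    shared dysregulated set when given — are returned (sorted).
    """
    counts: dict[str, int] = {}
    for si, sj in risk_pairs:
        ai = assoc_by_site.get(si, [])
        aj = assoc_by_site.get(sj, [])
        di = {r.gene_id: r.direction for r in ai}
        dj = {r.gene_id: r.direction for r in aj}
        shared = {g for g in di.keys() & dj.keys() if di[g] == dj[g]}
        for g in shared:
            counts[g] = counts.get(g, 0) + 1
    genes = {g for g, c in counts.items() if c >= min_pairs}
    if shared_de_genes is not None:
        genes &= set(shared_de_genes)
    return sorted(genes)


# ------------------------------------------------------------ signature


class SignatureModel(BaseEstimator):
    """Logistic gene-expression signature for tumor/normal classification.

    Fits a logistic model on log2(expression + 1) of the signature genes;
    scoring a cohort never refits (coefficients are frozen from training),
    mirroring validation on independent datasets. AUC is the trapezoidal
    area under the threshold-sweep ROC.
    """

    def __init__(self, genes: list[str], refit: bool = False):
        self.genes = list(genes)
        self.refit = refit

    @staticmethod
    def _design(values: pd.DataFrame, genes: list[str]) -> np.ndarray:
        return np.log2(values.loc[genes].to_numpy(float).T + 1.0)

    def fit(self, values: pd.DataFrame, labels: pd.Series):
        """``values`` genes x samples; ``labels`` 'tumor'/'normal' per sample."""
        missing = [g for g in self.genes if g not in values.index]
        if missing:
            log.warning("signature genes missing from training cohort: %s", missing)
        self.genes_ = [g for g in self.genes if g not in missing]
        if not self.genes_:
            raise ValueError("no signature genes present in the training cohort")
        y = (pd.Series(labels).reindex(values.columns) == "tumor").to_numpy(int)
        if y.min() == y.max():
            raise ValueError("training cohort has a single class")
        X = self._design(values, self.genes_)
        self.model_ = LogisticRegression(C=np.inf, max_iter=5000)
        self.model_.fit(X, y)
        self.coef_ = pd.Series(self.model_.coef_[0], index=self.genes_)
        self.intercept_ = float(self.model_.intercept_[0])
        self.train_auc_ = self.score_cohort(values, labels)["auc"]
        return self

    def decision_scores(self, values: pd.DataFrame) -> np.ndarray:
        genes = [g for g in self.genes_ if g in values.index]
        if len(genes) < len(self.genes_):
            dropped = sorted(set(self.genes_) - set(genes))
            raise ValueError(f"cohort missing signature genes: {dropped}")
        X = self._design(values, self.genes_)
        return X @ self.coef_.to_numpy() + self.intercept_

    def score_cohort(self, values: pd.DataFrame, labels: pd.Series) -> dict:
        """ROC/AUC of the frozen model on one cohort."""
        y = (pd.Series(labels).reindex(values.columns) == "tumor").to_numpy(int)
        if y.min() == y.max():
            raise ValueError("cohort has a single class; AUC undefined")
        if self.refit:
            clone = SignatureModel(self.genes_).fit(values, labels)
            scores = clone.decision_scores(values)
        else:
            scores = self.decision_scores(values)
        fpr, tpr = roc_curve_points(scores, y)
        return {"auc": trapezoid_auc(scores, y),
                "roc": pd.DataFrame({"fpr": fpr, "tpr": tpr}),
                "n": int(y.size)}


# ------------------------------------------------------------ copy number


def call_amplifications(segments: CopyNumberSegments, annotations: pd.DataFrame,
                        samples: list[str], threshold: float = 0.30) -> pd.DataFrame:
    """Sites x samples amplification indicator from segmented copy number.

    A site is amplified in a sample iff the covering segment's
    log2(CN/2) ratio is strictly greater than ``threshold``. When several
    segments cover a site the one with the larger overlap wins (exact ties:
    higher log2 ratio). Uncovered sites are 0.
    """
    seg = segments.data
    sites = list(annotations.index)
    out = pd.DataFrame(0, index=sites, columns=list(samples), dtype=np.int8)
    covered = pd.DataFrame(False, index=sites, columns=list(samples))
    for sample, sdf in seg.groupby("sample_id"):
        if sample not in out.columns:
            continue
        for site in sites:
            chrom = annotations.loc[site, "chrom"]
            pos = int(annotations.loc[site, "pos"])  # 1-based
            hits = sdf[(sdf["chrom"] == chrom) & (sdf["start"] < pos) & (pos <= sdf["end"])]
            if not len(hits):
                continue
            if len(hits) > 1:
                spans = (hits["end"] - hits["start"]).to_numpy()
                best = hits.iloc[np.lexsort((-hits["log2_ratio"].to_numpy(), -spans))[0]]
            else:
                best = hits.iloc[0]
            covered.loc[site, sample] = True
            if best["log2_ratio"] > threshold:
                out.loc[site, sample] = 1
    out.attrs["coverage"] = covered
    return out


def coamplification_test(pairs, amp: pd.DataFrame) -> pd.DataFrame:
    """Hypergeometric co-amplification test per site pair.

    For each pair, the joint amplified-sample count is tested against the
    upper-tail hypergeometric given each site's amplified-sample count over
    all samples; BH across pairs. A pair with a never-amplified site gets
    p = 1 and a flag.
    """
    n = amp.shape[1]
    m = amp.to_numpy(np.int64)
    idx = {s: i for i, s in enumerate(amp.index)}
    rows = []
    for si, sj in pairs:
        ki = int(m[idx[si]].sum())
        kj = int(m[idx[sj]].sum())
        k = int((m[idx[si]] & m[idx[sj]]).sum())
        if ki == 0 or kj == 0:
            rows.append({"site_i": si, "site_j": sj, "k_i": ki, "k_j": kj,
                         "co_amp": k, "p": 1.0, "never_amplified": True})
            continue
        p = hypergeom_upper_tail(k, kj, ki, n)
        rows.append({"site_i": si, "site_j": sj, "k_i": ki, "k_j": kj,
                     "co_amp": k, "p": p, "never_amplified": False})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr"] = bh_adjust(df["p"])
    return df
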
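"""Shared statistical primitives used across the pipeline.

All hypergeometric enrichment tests in the package (co-occurrence,
shared-gene, pathway enrichment, co-amplification) route through
:func:`hypergeom_upper_tail` so a single oracle validates every call site.
Multiple-testing correction is Benjamini–Hochberg throughout.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "hypergeom_upper_tail",
    "bh_adjust",
    "ranksum_test",
    "fisher_exact_2x2",
    "trapezoid_auc",
    "roc_curve_points",
]


def hypergeom_upper_tail(k: int, n_draws: int, n_successes: int, n_total: int) -> float:
    """Upper-tail probability P(X >= k) for X ~ Hypergeometric.

    Parameters
    ----------
    k : observed overlap.
    n_draws : size of the drawn set.
    n_successes : number of "success" items in the population.
    n_total : population size.
    """
    if not (0 <= k <= min(n_draws, n_successes)):
        if k > min(n_draws, n_successes):
            raise ValueError(
                f"overlap k={k} exceeds min(draws={n_draws}, successes={n_successes})"
            )
        raise ValueError(f"invalid overlap k={k}")
    if n_draws > n_total or n_successes > n_total:
        raise ValueError("draws/successes exceed population size")
    # sf(k-1) = P(X >= k)
    return float(sps.hypergeom.sf(k - 1, n_total, n_successes, n_draws))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ranksum_test(x, y, alternative: str = "two-sided") -> float:
    """Wilcoxon–Mann–Whitney rank-sum p-value.

    Exact enumeration when both groups are small (<= 8) and tie-free;
    mid-rank normal approximation with tie correction otherwise, matching
    common practice for larger groups.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if max(x.size, y.size) <= 8:
        no_ties = np.unique(pooled).size == pooled.size
        if no_ties:
            res = sps.mannwhitneyu(x, y, alternative=alternative, method="exact")
            return float(res.pvalue)
        # exact permutation distribution of U, valid under ties
        def stat(a, b):
            return sps.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic").statistic
        alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[alternative]
        res = sps.permutation_test(
            (x, y), stat, permutation_type="independent",
            alternative=alt, n_resamples=np.inf,
        )
        return float(res.pvalue)
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
    return float(res.pvalue)


def fisher_exact_2x2(table, alternative: str = "two-sided") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table. Returns (odds_ratio, p).

    Degenerate tables (an empty margin) are flagged by returning
    (nan, 1.0) rather than raising.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be a non-negative 2x2 array")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return float("nan"), 1.0
    orat, p = sps.fisher_exact(t, alternative=alternative)
    return float(orat), float(p)


def roc_curve_points(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """ROC curve (FPR, TPR) by threshold sweep over unique scores.

    Tied scores are processed as a block, which yields diagonal ROC
    segments; the trapezoidal area over those segments is then equivalent
    to counting tied score pairs as half-concordant.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    # cut only between distinct score values
    distinct = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    return fpr, tpr


def trapezoid_auc(scores, labels) -> float:
    """Area under the ROC curve by the trapezoidal rule.

    Equals the concordant-pair statistic with ties counted 1/2.
    """
    fpr, tpr = roc_curve_points(scores, labels)
    return float(np.trapezoid(tpr, fpr))
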
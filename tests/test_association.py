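"""Editing-associated genes, confounder screen, site classification."""

import math

import numpy as np
import pandas as pd
import pytest

from coedit.association import (
    EditingAssociationScreen,
    adjust_confounders,
    classify_sites,
    correlate_levels_expression,
    editing_associated_genes,
)
from coedit.datatypes import ClinicalTable, EditingMatrix, ExpressionBundle


def _bundle(values: pd.DataFrame, tumor_samples=None):
    tumor_samples = tumor_samples or list(values.columns)
    cls = pd.Series(["tumor" if s in tumor_samples else "normal"
                     for s in values.columns], index=values.columns)
    return ExpressionBundle(values=values, sample_class=cls)


def _edit(status: pd.DataFrame):
    return EditingMatrix(status=status)


class TestEditingAssociatedGenes:
    def test_small_separated_groups_fail_fdr(self):
        """3v3 complete separation: exact rank-sum p = 0.1 > 0.05, so the
        gene is excluded despite an 8-fold change."""
        samples = [f"p{i}" for i in range(6)]
        status = pd.DataFrame([[1, 1, 1, 0, 0, 0]], index=["s"], columns=samples)
        values = pd.DataFrame([[10, 11, 12, 1, 1, 2]], index=["g"], columns=samples,
                              dtype=float)
        recs = editing_associated_genes(_edit(status), _bundle(values), "s")
        assert recs == []

    def test_eight_v_eight_separated_included_up(self):
        """8v8 complete separation, FC=4: exact p = 2/C(16,8) passes."""
        samples = [f"p{i}" for i in range(16)]
        status = pd.DataFrame([[1] * 8 + [0] * 8], index=["s"], columns=samples)
        values = pd.DataFrame(
            [np.r_[np.linspace(40, 44, 8), np.linspace(10, 11, 8)]],
            index=["g"], columns=samples)
        recs = editing_associated_genes(_edit(status), _bundle(values), "s")
        assert len(recs) == 1
        rec = recs[0]
        assert rec.direction == "up"
        assert rec.wilcoxon_p == pytest.approx(2 / math.comb(16, 8))
        assert rec.fdr < 0.05 and rec.fold_change > 2

    def test_identical_distributions_excluded(self):
        samples = [f"p{i}" for i in range(16)]
        status = pd.DataFrame([[1] * 8 + [0] * 8], index=["s"], columns=samples)
        values = pd.DataFrame([list(range(8)) + list(range(8))],
                              index=["g"], columns=samples, dtype=float)
        assert editing_associated_genes(_edit(status), _bundle(values), "s") == []

    def test_below_min_group_skipped_not_raised(self):
        samples = [f"p{i}" for i in range(6)]
        status = pd.DataFrame([[1, 0, 0, 0, 0, 0]], index=["s"], columns=samples)
        values = pd.DataFrame(np.ones((1, 6)), index=["g"], columns=samples)
        assert editing_associated_genes(_edit(status), _bundle(values), "s") == []

    def test_label_swap_inverts_fold_change(self, rng):
        """Swapping edited and non-edited inverts FC and preserves p."""
        samples = [f"p{i}" for i in range(20)]
        status = pd.DataFrame([[1] * 10 + [0] * 10], index=["s"], columns=samples)
        flipped = pd.DataFrame([[0] * 10 + [1] * 10], index=["s"], columns=samples)
        values = pd.DataFrame(rng.lognormal(3, 1, size=(5, 20)),
                              index=[f"g{i}" for i in range(5)], columns=samples)
        a = editing_associated_genes(_edit(status), _bundle(values), "s",
                                     fdr_threshold=1.1, fold_threshold=1.0)
        b = editing_associated_genes(_edit(flipped), _bundle(values), "s",
                                     fdr_threshold=1.1, fold_threshold=1.0)
        fa = {r.gene_id: r for r in a}
        fb = {r.gene_id: r for r in b}
        for g in fa:
            assert fa[g].fold_change == pytest.approx(1 / fb[g].fold_change, rel=1e-6)
            assert fa[g].wilcoxon_p == pytest.approx(fb[g].wilcoxon_p)


class TestAdjustConfounders:
    def _cohort(self, n=200, shift=2.0, confounded=False, seed=0):
        rng = np.random.default_rng(seed)
        samples = [f"T{i}" for i in range(n)]
        edited = (rng.random(n) < 0.5).astype(int)
        stage = rng.choice([1.0, 2.0, 3.0, 4.0], n)
        log2 = rng.normal(5, 0.8, n)
        if confounded:
            # expression tracks stage; editing tracks stage; no direct link
            edited = (stage + rng.normal(0, 0.8, n) > 2.5).astype(int)
            log2 = log2 + 0.8 * stage
        else:
            log2 = log2 + shift * edited
        status = pd.DataFrame([edited], index=["s"], columns=samples)
        values = pd.DataFrame([2.0 ** log2], index=["g"], columns=samples)
        clin = ClinicalTable(pd.DataFrame({
            "age": rng.normal(60, 9, n).round(), "gender": rng.choice(["male", "female"], n),
            "bmi": rng.normal(25, 3, n), "stage": stage,
            "grade": rng.choice([1.0, 2.0, 3.0], n), "afp": rng.lognormal(3, 1, n),
            "os_time": rng.exponential(900, n) + 1, "os_event": rng.integers(0, 2, n),
        }, index=samples))
        return _edit(status), _bundle(values), clin

    def test_planted_shift_passes_adjustment(self):
        hits = 0
        for seed in range(10):
            edit, expr, clin = self._cohort(shift=2.0, seed=seed)
            recs = editing_associated_genes(edit, expr, "s")
            assert recs, "planted shift should be a rank-sum candidate"
            recs = adjust_confounders(recs, edit, expr, clin)
            hits += recs[0].adjusted_pass
        assert hits >= 9

    def test_stage_confounded_association_rejected_more_often(self):
        passes = 0
        tested = 0
        for seed in range(20):
            edit, expr, clin = self._cohort(confounded=True, seed=seed)
            recs = editing_associated_genes(edit, expr, "s")
            if not recs:
                continue
            recs = adjust_confounders(recs, edit, expr, clin)
            tested += 1
            passes += recs[0].adjusted_pass
        assert tested >= 5
        assert passes / tested <= 0.4  # most confounded hits are screened out

    def test_null_pass_rate_near_nominal(self):
        passes = tested = 0
        for seed in range(60):
            edit, expr, clin = self._cohort(shift=0.0, seed=1000 + seed)
            # force the gene through as a candidate to measure the screen alone
            recs = editing_associated_genes(edit, expr, "s", fdr_threshold=1.1,
                                            fold_threshold=1.0)
            recs = adjust_confounders(recs, edit, expr, clin)
            tested += 1
            passes += recs[0].adjusted_pass
        assert passes / tested <= 0.12


class TestClassifySites:
    def test_gain_site_with_exact_fisher(self):
        """40/100 tumors vs 0/50 normals: Fisher's p is the single-table
        tail C(100,50)... computed here by scipy; frequency in normal is
        0 < 5% so the site is a tumor gain."""
        tum = pd.DataFrame([[1] * 40 + [0] * 60], index=["s"],
                           columns=[f"T{i}" for i in range(100)])
        nor = pd.DataFrame([[0] * 50], index=["s"],
                           columns=[f"N{i}" for i in range(50)])
        out = classify_sites(tum, nor)
        assert out[0].site_class == "hcc_gain"
        assert out[0].fisher_fdr < 0.05
        # oracle: hypergeometric point mass sum over tables at least as extreme
        from tests.test_stats import enum_fisher_two_sided
        assert out[0].fisher_p == pytest.approx(
            enum_fisher_two_sided([[40, 60], [0, 50]]), rel=1e-6)

    def test_equal_frequency_is_none(self):
        tum = pd.DataFrame([[1] * 10 + [0] * 90], index=["s"],
                           columns=[f"T{i}" for i in range(100)])
        nor = pd.DataFrame([[1] * 5 + [0] * 45], index=["s"],
                           columns=[f"N{i}" for i in range(50)])
        assert classify_sites(tum, nor)[0].site_class == "none"

    def test_paired_level_change_dys_edit_limit(self):
        """Levels uniformly +0.3 in 10/10 pairs with near-zero spread."""
        cols_t = [f"T{i}" for i in range(10)]
        cols_n = [f"N{i}" for i in range(10)]
        tum = pd.DataFrame([[1] * 10], index=["s"], columns=cols_t)
        nor = pd.DataFrame([[1] * 10], index=["s"], columns=cols_n)
        rng = np.random.default_rng(0)
        base = rng.uniform(0.2, 0.4, 10)
        lt = pd.DataFrame([base + 0.3 + rng.normal(0, 1e-4, 10)], index=["s"],
                          columns=cols_n)  # paired by normal column order
        ln = pd.DataFrame([base], index=["s"], columns=cols_n)
        out = classify_sites(tum, nor, paired_levels=(lt, ln))
        assert out[0].site_class == "dys_edit"
        assert out[0].n_supporting_pairs == 10

    def test_too_few_pairs_ineligible_for_dys_edit(self):
        cols_n = ["N0"]
        tum = pd.DataFrame([[1, 1]], index=["s"], columns=["T0", "T1"])
        nor = pd.DataFrame([[1]], index=["s"], columns=cols_n)
        lt = pd.DataFrame([[0.9]], index=["s"], columns=cols_n)
        ln = pd.DataFrame([[0.2]], index=["s"], columns=cols_n)
        out = classify_sites(tum, nor, paired_levels=(lt, ln))
        assert out[0].site_class != "dys_edit"


class TestCorrelateLevels:
    def _setup(self, frac_edited, prop=True, n=40):
        samples = [f"T{i}" for i in range(n)]
        k = int(frac_edited * n)
        status = pd.DataFrame([[1] * k + [0] * (n - k)], index=["chr1:5:G"],
                              columns=samples)
        rng = np.random.default_rng(3)
        levels = pd.DataFrame([np.r_[rng.uniform(0.2, 0.8, k), [np.nan] * (n - k)]],
                              index=["chr1:5:G"], columns=samples)
        if prop:
            vals = 10 * levels.iloc[0].fillna(0.0)
        else:
            vals = pd.Series(rng.lognormal(2, 1, n), index=samples)
        values = pd.DataFrame([vals], index=["G"], columns=samples)
        ann = pd.DataFrame({"chrom": ["chr1"], "pos": [5], "strand": ["+"],
                            "gene": ["G"]}, index=["chr1:5:G"])
        edit = EditingMatrix(status=status, levels=levels, annotations=ann)
        return edit, _bundle(values)

    def test_proportional_levels_give_r_one(self):
        edit, expr = self._setup(0.5, prop=True)
        df = correlate_levels_expression(edit, expr)
        assert df.iloc[0]["pearson_r"] == pytest.approx(1.0)
        assert df.iloc[0]["p"] < 1e-10

    def test_low_frequency_site_excluded(self):
        edit, expr = self._setup(0.20, prop=True)
        df = correlate_levels_expression(edit, expr, min_edit_frac=0.25)
        assert len(df) == 0


def test_screen_recovers_planted_associations(small_cohort):
    """End-to-end: the estimator finds the planted site-gene links."""
    screen = EditingAssociationScreen().fit(
        small_cohort["editing"], small_cohort["expression"], small_cohort["clinical"])
    truth_pairs = {(s, g) for s, g, _ in small_cohort["truth"].assoc_genes}
    found = {(r.site_id, r.gene_id) for r in screen.records_
             if r.adjusted_pass is not False}
    recovered = len(found & truth_pairs) / len(truth_pairs)
    assert recovered >= 0.8
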
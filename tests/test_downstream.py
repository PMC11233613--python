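"""Differential expression stand-in, enrichment, signature, copy number."""

import math

import numpy as np
import pandas as pd
import pytest

from coedit.datatypes import CopyNumberSegments, GeneSetCollection
from coedit.downstream import (
    RankSumDE,
    SignatureModel,
    call_amplifications,
    coamplification_test,
    coediting_associated_genes,
    pathway_enrichment,
    shared_dysregulated_intersection,
    size_factors,
)


class _Rec:
    def __init__(self, gene_id, direction):
        self.gene_id = gene_id
        self.direction = direction


def _counts(rng, n_genes=300, n_a=10, n_b=10, de=(), fold=4.0):
    mu = rng.lognormal(4, 1, n_genes)
    a = rng.poisson(mu[:, None], (n_genes, n_a)).astype(float)
    b = rng.poisson(mu[:, None], (n_genes, n_b)).astype(float)
    for g in de:
        a[g] = rng.poisson(mu[g] * fold, n_a)
    genes = [f"g{i}" for i in range(n_genes)]
    cols_a = [f"A{i}" for i in range(n_a)]
    cols_b = [f"B{i}" for i in range(n_b)]
    df = pd.DataFrame(np.hstack([a, b]).astype(int), index=genes,
                      columns=cols_a + cols_b)
    return df, cols_a, cols_b


class TestSizeFactors:
    def test_equal_libraries_give_unit_factors(self, rng):
        counts = pd.DataFrame(rng.poisson(50, (100, 6)),
                              index=[f"g{i}" for i in range(100)],
                              columns=[f"s{i}" for i in range(6)])
        sf = size_factors(counts)
        assert np.allclose(sf, 1.0, atol=0.15)

    def test_scaled_library_detected(self, rng):
        counts = pd.DataFrame(rng.poisson(50, (200, 4)),
                              index=[f"g{i}" for i in range(200)],
                              columns=list("abcd"))
        counts["d"] = (counts["d"] * 3).astype(int)
        sf = size_factors(counts)
        assert sf["d"] / sf["a"] == pytest.approx(3.0, rel=0.1)

    def test_fallback_to_totals_when_no_common_gene(self):
        counts = pd.DataFrame([[5, 0], [0, 5]], index=["g1", "g2"],
                              columns=["a", "b"])
        with pytest.warns(UserWarning, match="total-count"):
            sf = size_factors(counts)
        assert np.allclose(sf, 1.0)


class TestRankSumDE:
    def test_fourfold_gene_is_up_candidate(self, rng):
        counts, a, b = _counts(rng, n_a=15, n_b=15, de=[0], fold=4.0)
        res = RankSumDE().fit(counts, a, b).results_
        assert res.loc["g0", "log2_fc"] == pytest.approx(2.0, abs=0.5)
        assert res.loc["g0", "status"] == "up"

    def test_identical_groups_zero_hits(self, rng):
        counts, a, b = _counts(rng)
        de = RankSumDE().fit(counts, a, b)
        assert (de.results_["status"] == "ns").all()

    def test_label_swap_negates_lfc_preserves_p(self, rng):
        counts, a, b = _counts(rng, de=[0, 1], fold=3.0)
        r1 = RankSumDE().fit(counts, a, b).results_
        r2 = RankSumDE().fit(counts, b, a).results_
        np.testing.assert_allclose(r1["log2_fc"], -r2["log2_fc"], atol=1e-9)
        np.testing.assert_allclose(r1["p"], r2["p"], rtol=1e-9)

    def test_planted_recovery_sensitivity_and_fdr(self):
        """200 planted 4-fold genes among 5,000, 20 vs 20 samples."""
        rng = np.random.default_rng(17)
        counts, a, b = _counts(rng, n_genes=5000, n_a=20, n_b=20,
                               de=range(200), fold=4.0)
        de = RankSumDE().fit(counts, a, b)
        called = de.up_genes() | de.down_genes()
        truth = {f"g{i}" for i in range(200)}
        sensitivity = len(called & truth) / len(truth)
        false_frac = len(called - truth) / max(len(called), 1)
        assert sensitivity >= 0.90
        assert false_frac <= 0.05

    def test_too_few_samples_rejected(self, rng):
        counts, a, b = _counts(rng, n_a=2, n_b=5)
        with pytest.raises(ValueError, match=">= 3"):
            RankSumDE().fit(counts, a, b)


class TestSharedIntersection:
    def _table(self, statuses):
        return pd.DataFrame({"status": statuses},
                            index=[f"g{i}" for i in range(len(statuses))])

    def test_direction_consistency_required(self):
        a = self._table(["up", "up", "down", "ns"])
        b = self._table(["up", "down", "down", "up"])
        out = shared_dysregulated_intersection(a, b)
        assert out["up"] == {"g0"}
        assert out["down"] == {"g2"}
        assert out["all"] == {"g0", "g2"}

    def test_disjoint_sets_empty(self):
        a = self._table(["up", "ns"])
        b = self._table(["ns", "down"])
        out = shared_dysregulated_intersection(a, b)
        assert out["all"] == set()


class TestPathwayEnrichment:
    def test_tail_matches_direct_summation(self):
        universe = [f"g{i}" for i in range(1000)]
        coll = GeneSetCollection(sets={"S": set(universe[:50])})
        query = set(universe[:10]) | set(universe[500:510])  # overlap 10 of 20
        out = pathway_enrichment(query, coll, universe)
        oracle = sum(math.comb(50, x) * math.comb(950, 20 - x)
                     for x in range(10, 21)) / math.comb(1000, 20)
        assert out.iloc[0]["p"] == pytest.approx(oracle, rel=1e-9)
        assert out.iloc[0]["overlap"] == 10

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(100)]
        coll = GeneSetCollection(sets={"S": set(universe[:20])})
        out = pathway_enrichment(set(universe[50:60]), coll, universe)
        assert out.iloc[0]["p"] == 1.0

    def test_query_equals_set_is_minimal_p(self):
        universe = [f"g{i}" for i in range(60)]
        coll = GeneSetCollection(sets={"S": set(universe[:8])})
        p_full = pathway_enrichment(set(universe[:8]), coll, universe).iloc[0]["p"]
        # any other query of size 8 has larger or equal tail p
        p_other = pathway_enrichment(set(universe[4:12]), coll, universe).iloc[0]["p"]
        assert p_full <= p_other
        assert p_full == pytest.approx(1 / math.comb(60, 8))


class TestCoeditingAssociatedGenes:
    def _assoc(self):
        return {
            "s1": [_Rec("G", "up"), _Rec("X", "up")],
            "s2": [_Rec("G", "up"), _Rec("Y", "down")],
            "s3": [_Rec("G", "up")],
            "s4": [_Rec("G", "up")],
            "s5": [_Rec("G", "down")],
            "s6": [_Rec("G", "down")],
        }

    def test_gene_in_three_pair_sets_included(self):
        pairs = [("s1", "s2"), ("s3", "s4"), ("s1", "s3"), ("s2", "s4")]
        out = coediting_associated_genes(pairs, self._assoc(),
                                         shared_de_genes={"G"}, min_pairs=3)
        assert out == ["G"]

    def test_gene_below_min_pairs_excluded(self):
        pairs = [("s1", "s2"), ("s3", "s4")]
        assert coediting_associated_genes(pairs, self._assoc(),
                                          shared_de_genes={"G"}, min_pairs=3) == []

    def test_direction_mismatch_between_sites_not_counted(self):
        pairs = [("s1", "s5"), ("s2", "s6"), ("s3", "s5")]
        assert coediting_associated_genes(pairs, self._assoc(), min_pairs=1) == []

    def test_non_de_gene_excluded(self):
        pairs = [("s1", "s2"), ("s3", "s4"), ("s1", "s3")]
        assert coediting_associated_genes(pairs, self._assoc(),
                                          shared_de_genes={"Z"}, min_pairs=3) == []

    def test_no_risk_pairs_empty(self):
        assert coediting_associated_genes([], self._assoc()) == []


class TestSignature:
    def _cohort(self, rng, n=200, sep=3.0, genes=("G1", "G2")):
        labels = pd.Series(["tumor"] * (n // 2) + ["normal"] * (n // 2),
                           index=[f"s{i}" for i in range(n)])
        vals = {}
        for g in genes:
            base = rng.lognormal(3, 0.5, n)
            base[: n // 2] *= 2 ** sep
            vals[g] = base
        values = pd.DataFrame(vals, index=labels.index).T
        return values, labels

    def test_separable_signature_auc_one(self, rng):
        values, labels = self._cohort(rng, sep=6.0)
        model = SignatureModel(["G1", "G2"]).fit(values, labels)
        assert model.train_auc_ == pytest.approx(1.0)

    def test_permuted_labels_auc_near_half(self):
        aucs = []
        for seed in range(15):
            r = np.random.default_rng(seed)
            values, labels = self._cohort(r, n=400, sep=0.0)
            model = SignatureModel(["G1", "G2"]).fit(values, labels)
            aucs.append(model.train_auc_)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_frozen_coefficients_on_held_out_cohort(self, rng):
        values, labels = self._cohort(rng, sep=4.0)
        model = SignatureModel(["G1", "G2"]).fit(values, labels)
        v2, l2 = self._cohort(np.random.default_rng(99), n=100, sep=4.0)
        before = model.coef_.copy()
        out = model.score_cohort(v2, l2)
        pd.testing.assert_series_equal(model.coef_, before)
        assert out["auc"] > 0.9

    def test_single_class_cohort_rejected(self, rng):
        values, labels = self._cohort(rng)
        with pytest.raises(ValueError, match="single class"):
            model = SignatureModel(["G1"]).fit(values, labels)
            model.score_cohort(values, pd.Series("tumor", index=labels.index))


class TestCopyNumber:
    def _setup(self):
        ann = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [100, 500],
                            "gene": ["GA", "GB"]}, index=["x", "y"])
        seg = pd.DataFrame([
            ("T1", "chr1", 0, 300, math.log2(3 / 2)),   # CN=3 -> amplified
            ("T1", "chr1", 300, 600, 0.0),              # CN=2 -> neutral
            ("T2", "chr1", 0, 300, 0.30),               # exactly at threshold
            ("T2", "chr1", 300, 600, 0.31),
        ], columns=["sample_id", "chrom", "start", "end", "log2_ratio"])
        return CopyNumberSegments(seg), ann

    def test_threshold_semantics(self):
        segments, ann = self._setup()
        amp = call_amplifications(segments, ann, ["T1", "T2"])
        assert amp.loc["x", "T1"] == 1     # log2(3/2) ~ 0.585 > 0.30
        assert amp.loc["y", "T1"] == 0     # log2(1) = 0
        assert amp.loc["x", "T2"] == 0     # exactly 0.30 is NOT amplified
        assert amp.loc["y", "T2"] == 1     # 0.31 > 0.30

    def test_uncovered_site_zero_with_flag(self):
        segments, ann = self._setup()
        ann2 = pd.concat([ann, pd.DataFrame({"chrom": ["chr9"], "pos": [5],
                                             "gene": ["GC"]}, index=["z"])])
        amp = call_amplifications(segments, ann2, ["T1"])
        assert amp.loc["z", "T1"] == 0
        assert not amp.attrs["coverage"].loc["z", "T1"]

    def test_coamplification_same_five_samples(self):
        samples = [f"T{i}" for i in range(10)]
        amp = pd.DataFrame(0, index=["x", "y"], columns=samples)
        amp.loc["x", samples[:5]] = 1
        amp.loc["y", samples[:5]] = 1
        out = coamplification_test([("x", "y")], amp)
        assert out.iloc[0]["p"] == pytest.approx(1 / 252)

    def test_disjoint_amplification_p_one(self):
        samples = [f"T{i}" for i in range(10)]
        amp = pd.DataFrame(0, index=["x", "y"], columns=samples)
        amp.loc["x", samples[:5]] = 1
        amp.loc["y", samples[5:]] = 1
        assert coamplification_test([("x", "y")], amp).iloc[0]["p"] == 1.0

    def test_never_amplified_site_flagged(self):
        samples = [f"T{i}" for i in range(6)]
        amp = pd.DataFrame(0, index=["x", "y"], columns=samples)
        amp.loc["x"] = 1
        out = coamplification_test([("x", "y")], amp)
        assert out.iloc[0]["never_amplified"] and out.iloc[0]["p"] == 1.0

    def test_planted_coamp_recovered(self, small_cohort):
        editing = small_cohort["editing"]
        segments = small_cohort["segments"]
        tumor = [s for s in editing.sample_ids if s.startswith("T")]
        cfg = small_cohort["config"]
        # plant a co-amplified pair in a fresh copy of the cohort config
        from coedit.simulate import generate_cohort
        sites = cfg.site_ids()
        cfg2 = type(cfg)(**{**cfg.__dict__})
        cfg2.cn_coamp_pairs = [(sites[-1], sites[-2], 0.3)]
        editing2, _, _, segments2, truth2 = generate_cohort(cfg2)
        amp = call_amplifications(segments2, editing2.annotations, tumor)
        pairs = [(sites[-1], sites[-2]), (sites[0], sites[5])]
        out = coamplification_test(pairs, amp).set_index(["site_i", "site_j"])
        assert out.loc[(sites[-1], sites[-2]), "fdr"] < 0.05
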
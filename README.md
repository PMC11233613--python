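# coedit

Inference and downstream analysis of **A-to-I RNA co-editing networks**
in tumor cohorts.

A-to-I editing — deamination of adenosine to inosine by ADAR enzymes — is
pervasive in tumor transcriptomes, and pairs of editing sites are often
edited *together* in the same patients far more than their individual
editing frequencies explain. `coedit` is for computational biologists who
have a binary editing-status matrix (sites × samples) plus expression,
clinical and copy-number tables for the same cohort, and want to:

1. infer which site pairs are genuine co-editing interactions,
2. characterize the resulting network (scale-free fit, hubs, dense
   modules, closeness of disease-related sites),
3. find co-editing pairs that predict overall survival and stratify
   patients into risk groups, and
4. run the downstream comparisons (differential expression, pathway
   enrichment, a gene-expression classifier with ROC/AUC, copy-number
   co-amplification).

## The statistic at the core

For sites *i, j* over *N* tumor samples with *k_i*, *k_j* edited samples
and co-count *k*, the co-occurrence screen tests

  p = P(X ≥ k),  X ~ Hypergeometric(N, k_i, k_j)

over all pairs co-edited in ≥ 3 samples (BH, FDR < 0.05). Survivors face
a permutation null that preserves **both margins** of the editing matrix
(per-site frequency and per-sample burden) via curveball trades, with
empirical p = (1 + #{permuted co-count ≥ k}) / (B + 1), B = 1000. Finally,
pairs must share direction-consistent *editing-associated genes* (genes
differentially expressed between edited and non-edited carriers of each
site, after a logistic adjustment for age, gender, BMI, stage and grade)
beyond hypergeometric expectation. Surviving pairs form the network.
Risk pairs are then screened with staged Cox proportional-hazards models
(univariate → adjusted for the two single-site indicators → additionally
adjusted for clinical covariates), requiring p < 0.05 and HR > 1
throughout. See `docs/methods.md` for the full model description.

Every stage is testable without access to patient data: the
`coedit.simulate` module generates cohorts with planted co-editing pairs,
planted editing-associated genes, planted hazard effects and planted
co-amplified loci, with marginals preserved exactly and a single seed
controlling everything.

## Worked example

Simulate a cohort with 6 planted co-editing pairs (2 of them carrying a
survival hazard) and run the full pipeline:

```python
from coedit.pipeline import RunConfig, run_pipeline
from coedit.simulate import default_planted_config

sim = default_planted_config(seed=0, n_tumor=150, n_sites=60,
                             n_pairs=6, n_hazard_pairs=2)
sim.n_genes = 300
report = run_pipeline(RunConfig(simulate=sim, B=500, seed=17))
print(report.stage_counts)
```

prints (abridged):

```
n_tumor: 150            n_candidate_pairs: 1680
n_edges: 5              n_nodes: 10
n_risk_pairs: 1         n_high_risk: 22
n_low_risk: 128         risk_group_logrank_p: 2.6e-07
```

Reading: of 1,680 candidate pairs, 5 survive all three filters — all of
them planted (at this small cohort size one planted pair lacks the power
to pass every screen; recovery reaches ≥ 90% at the 300-tumor study
size). One pair also survives the three-stage survival screen, and the 22
patients carrying it have markedly worse overall survival (log-rank
p ≈ 2.6e-07) than the 128 who do not.

The same run is available from the shell:

```bash
coedit simulate --out cohort/ --seed 0
echo '{"simulate": {"n_tumor": 150, "n_sites": 60, "n_genes": 300}, "B": 500}' > run.json
coedit run --config run.json --seed 17
```

Estimator-style classes are available for each stage
(`CoEditingNetwork`, `EditingAssociationScreen`, `PairSurvivalScreen`,
`RankSumDE`, `SignatureModel`) with sklearn `fit`/`get_params` semantics
and fitted attributes like `network_`, `risk_pairs_`, `results_`.

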
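# Methods

## Problem and model

`coedit` infers *co-editing interactions* between A-to-I RNA editing sites
from a binary sites × samples editing matrix of a tumor cohort, then
carries the inferred network through topological characterization,
survival screening, and downstream expression / copy-number comparisons.

Two sites are called a co-editing pair when their joint editing across
tumor samples exceeds what their marginal editing frequencies explain.
The network is built in four steps:

1. **Candidate screen.** All unordered site pairs co-edited in ≥ 3 tumor
   samples are tested with an upper-tail hypergeometric test: with N
   samples, k_i and k_j edited samples per site and co-count k, the
   p-value is P(X ≥ k) for X ~ Hypergeom(N, k_i, k_j). BH across pairs,
   FDR < 0.05.
2. **Permutation null.** Editing matrices are randomized preserving every
   row sum (editing frequency per site) and every column sum (editing
   burden per sample) using a curveball trade chain. The empirical
   p-value of a pair is (1 + #{permuted co-count ≥ observed}) / (B + 1)
   with B = 1000; BH, FDR < 0.05. The add-one convention keeps the p
   strictly positive and valid. Permutations are computed only for pairs
   surviving step 1, which bounds cost without changing the statistics of
   the survivors.
3. **Shared-gene filter.** Per site, *editing-associated genes* are genes
   whose expression differs between edited and non-edited tumor samples
   (two-sided rank-sum, BH per site, FDR < 0.05, fold change > 2 in
   either direction; fold change uses a pseudocount of 0.01 on both group
   means because FPKM zeros are common). Candidates are re-screened by a
   logistic model of editing status on log2 expression adjusted for age,
   gender, BMI, stage and grade (complete case; BH on the expression
   coefficient). A surviving pair must share direction-consistent
   associated genes (up∩up plus down∩down) beyond hypergeometric
   expectation over the universe of genes screened; BH, FDR < 0.05.
   Pairs with an empty association set on either side cannot share genes
   and are dropped.
4. **Assembly** into a simple undirected graph; edges carry all p/FDR
   values and counts.

### Design choices in the network stage

- *Coupling for planted/joint editing* (see generator below) and the
  *empirical-p tail*: enrichment (≥) is the alternative of interest, so
  the upper tail is used.
- *Logistic adjustment orientation*: editing status is the outcome and
  expression the predictor, because editing is the binary variable; the
  alternative orientation is statistically similar for a single binary
  adjustment but this one is well defined with continuous covariates.
- *Shared-gene universe*: the genes screened for both sites (with the
  bundled expression data this is all retained genes), so the test
  conditions on testability.
- *Curveball chain budget*: burn-in of 2 × and thinning of 1 × max(5 ×
  n_rows, 100) trades between successive matrices. Each trade exchanges
  exclusive column memberships between two random rows, so every matrix
  in the ensemble preserves both margins exactly; uniformity of the
  stationary distribution is the standard curveball result. The
  calibration check (fraction of null empirical p below 0.05 ≈ 5% on an
  exchangeable matrix) is part of the acceptance suite.

## Topology

- **Power-law diagnostic**: least-squares regression of log10 P(k) on
  log10 k over observed positive degrees, reporting R² and −slope as the
  exponent. The regression (not maximum likelihood) is used because the
  diagnostic of interest is the log-log linearity R². Fits with < 3
  distinct degrees are refused.
- **Hubs**: top 10% of nodes by degree (ceil); ties at the cutoff are all
  included and flagged.
- **MCODE**: vertex weight = k × density of the highest k-core of the
  closed neighborhood (0 below the degree cutoff 3); complexes grow
  breadth-first from the highest-weight unassigned vertex, admitting
  unassigned neighbors with weight ≥ seed_weight × (1 − 0.2), to depth
  100; complexes lacking a 3-core are discarded (their vertices become
  seedable again), and the haircut iteratively removes singly-connected
  members. One deliberate refinement over the textbook expansion rule:
  **expansion never enters vertices whose neighborhood core level is
  below the seed's**. Without this guard a single bridge edge lets a
  complex seeded in a K7 absorb an adjacent K6 (the bridge endpoint's
  weight, 5, is within 20% of the seed weight 6); with it, distinct
  cliques are reported as distinct modules, which is the behavior users
  of module detection expect. Fluff is off (not part of the documented
  parameter set). Modules are ranked by density × size.
- **Shortest-path permutation test**: mean pairwise shortest-path length
  within a node set, excluding (and counting) pairs in different
  components, against B same-size node sets drawn uniformly from all
  network nodes; add-one empirical p.

## Site classification

Tumor-gain / tumor-loss sites: two-sided Fisher's exact test on edited
counts tumor vs normal (BH, FDR < 0.05) with the additional requirement
that the editing frequency is < 5% in normal (gain) or tumor (loss)
samples. Dysregulated-editing sites: paired t-test on editing levels over
matched tumor/normal pairs (BH; FDR < 0.2 and p < 0.01) with |level
change| > 0.25 in ≥ 2 pairs; sites with < 2 complete pairs are ineligible.

## Survival screening

Cox proportional-hazards fits use lifelines (partial likelihood, Efron
ties, Newton optimization). A co-editing pair is screened in three
stages: univariate on the co-edited indicator; adjusted for the two
single-site editing indicators (the minimal model isolating the pair
effect beyond its constituents); additionally adjusted for age, gender,
stage, grade and log1p(AFP), complete case. A *risk pair* must have
p < 0.05 and HR > 1 at every stage. Pairs whose indicator duplicates a
single-site indicator are non-identifiable and skipped with a reason.
Patients carrying ≥ 1 risk pair form the high-risk group; cumulative
burden is reported by the number of risk pairs carried. Separation /
monotone-likelihood fits are retried with a small ridge penalty and
flagged. Note the duplication-invariance caveat: duplicating every
subject introduces event-time ties, so under Efron weights the refit
coefficients match to ~1e-3 rather than exactly (exactly under Breslow).

## Downstream

- **Differential expression** is a deliberately simple documented
  stand-in, not a negative-binomial GLM: median-of-ratios size factors
  (geometric-mean reference over genes with all-positive counts, total-
  count fallback with warning), log2 fold change of normalized means with
  pseudocount 1, two-sided rank-sum p, BH; thresholds FDR < 0.05 and
  |log2FC| > 1. Downstream claims (thresholding, direction-consistent
  intersection, signature construction) are structural and do not depend
  on the count model.
- **Pathway enrichment**: upper-tail hypergeometric per gene set against
  a declared universe, sets intersected with the universe, BH.
- **Co-editing-associated genes**: per risk pair, the direction-
  consistent intersection of the two sites' associated genes; genes in
  ≥ 3 per-pair sets and in the shared dysregulated set feed the
  signature.
- **Signature**: logistic regression on log2(expr + 1); held-out cohorts
  are scored with frozen training coefficients (refit optional). ROC by
  threshold sweep over unique scores; AUC by trapezoid, which equals
  concordance-pair counting with ties worth 1/2.
- **Copy number**: a site is amplified when its covering segment has
  log2(CN/2) strictly > 0.30; multi-segment overlaps resolve to the
  larger overlap (ties: higher log2). Co-amplification per pair is the
  same upper-tail hypergeometric as the co-occurrence screen (one shared
  implementation), BH across pairs.

## Synthetic cohort generator

The generator emulates the statistical structure of a tumor RNA-seq
cohort with matched normals; it is the ground-truth source for every
test. Defaults: 300 tumors, 50 normals, 200 sites, 500 genes.

- **Editing**: per-site marginal editing probability Uniform(0.10,
  0.40). A planted pair with strength b ∈ [0, 1] draws, per sample, from
  the comonotone coupling with probability b and independently otherwise,
  giving P(both) = b·min(p_i, p_j) + (1 − b)·p_i·p_j with marginals
  preserved exactly — one interpretable knob from independence (b = 0) to
  maximal overlap (b = 1). Editing levels are Uniform(0.1, 0.9) where
  edited, missing otherwise.
- **Expression**: log2 baseline Normal(μ_g, 0.8) with μ_g ~ Uniform(3,
  8); planted association effects add their log2 shift in edited
  samples; counts are Poisson around the expression means (the DE
  stand-in is rank-based, so the count law is secondary).
- **Survival**: time-to-event Exponential with rate (1/1000 per day) ×
  exp(Σ carried log-HRs), independent Exponential censoring at 1/4000
  per day (~20% censoring); age, gender, BMI, stage, grade drawn from
  simple demographic distributions, AFP log-normal with 10% missingness.
- **Copy number**: single-base segments at every site locus, one extra
  copy (log2 3/2 ≈ 0.585) at a 5% background rate; planted co-amplified
  pairs are amplified jointly with their stated probability.

What the generator does *not* emulate: linkage between neighboring sites
beyond planted pairs, ADAR-motif sequence context, library-size and
batch artifacts, non-proportional hazards, subclonal copy-number states.
Passing tests therefore demonstrate the statistical machinery recovers
planted structure under its own assumptions, not performance on real
cohorts.

## Problem sizes and study conditions used by the test and acceptance runs

- Planted-network recovery: 300 tumors, 200 sites, 20 planted pairs at
  b = 0.8, each pair sharing 5 up-shifted (log2 +2) associated genes;
  B = 1000, FDR 0.05. Expected: ≥ 90% of planted pairs recovered, ≤ 5%
  of reported edges non-planted.
- Permutation-null calibration: 50 sites × 400 samples at constant
  marginal 0.5 (constant marginals make the observed matrix exchangeable
  with the margin-fixed null), 200 pairs, B = 1000.
- Cox recovery: planted log-HR 1.0, n = 500, ~20% censoring, mean over
  50 seeds within ±0.15; null Wald p checked uniform over 200 replicates.
- Survival screen: one planted hazard pair (log-HR 1.0) in an n = 800
  cohort with site marginals 0.5. The sample size was fixed a priori by a
  power analysis of the single-site-adjusted stage: the pair coefficient
  is identified only by samples edited at exactly one site, so cohorts
  with strong co-occurrence (b near 1) cannot separate the pair effect
  from its constituent sites regardless of effect size.
- Null end-to-end run: 150 tumors, 60 sites, 300 genes, no planted
  structure, B = 500.

## Numerical conventions

- Rank-sum tests: exact (permutation enumeration under ties) for groups
  ≤ 8, mid-rank normal approximation otherwise.
- All multiple-testing corrections are Benjamini–Hochberg.
- Degenerate Fisher tables (an empty margin) return p = 1 with an
  undefined odds ratio rather than raising.
- BED input is 0-based half-open; every in-memory or reported position is
  1-based. Copy-number segments are 1-based inclusive on disk, half-open
  internally.
- A single run seed fans out to per-stage child seeds via
  `numpy.random.SeedSequence`; identical config + seed gives a
  byte-identical run report.

## Known limitations

- The DE stand-in has lower power than a count-model test at small n and
  is rank-based, so it cannot call genes whose change is purely in
  dispersion.
- The permutation chain assumes the curveball trades mix within the
  thinning budget; pathological margins (near-degenerate matrices) mix
  slowly and are flagged only in the fully degenerate case.
- The survival screen treats editing as fixed at baseline; no
  time-varying exposure or competing risks.
- MCODE module membership is greedy and order-dependent in ties; ties are
  broken lexicographically for determinism.
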
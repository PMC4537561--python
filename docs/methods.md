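# Methods

`acidnet` implements a guide-gene-anchored weighted co-expression analysis of
two-genotype RNA-seq expression data, modelled on the study design it
emulates: mature apple fruit of contrasting acidity, 17 usable samples of
genotype *Ma_* (at least one functional *Ma1* allele, normal/high acidity)
and 12 of *mama* (low acidity), with per-sample malate (mg/g FW), titratable
acidity (mg/ml) and juice pH. The guide gene is *Ma1* (MDP0000252114), an
ALMT1-like vacuolar malate transporter at the *Ma* locus; every selection
threshold that the analysis does not fix a priori is calibrated on the
guide's own observed statistics.

## Pipeline stages

**Expressed-gene filter.** A gene is expressed when its mean RPKM exceeds
0.3 (strict) in at least one genotype group; the Venn partition of the
expressed set (both groups / A only / B only) is reported. Group means are
unweighted arithmetic means over replicate samples.

**Trait-associated gene selection (FAAGs).** The union of two rules:

1. *Differential expression.* A weighted two-group proportions test in the
   moment-based beta-binomial style: each sample column is treated as a
   library, a gene's per-sample proportion is its RPKM over the column
   total, and group means and variances of those proportions are weighted
   by the column totals (unbiased reliability-weight variance of the
   weighted mean). The statistic is the difference of weighted group means
   over the pooled standard error, referred to a t distribution with
   Welch–Satterthwaite degrees of freedom. P-values are Benjamini–Hochberg
   adjusted (step-up, implemented directly and oracle-tested); DEGs require
   `P_FDR < 0.05` and an RPKM range (max − min over all samples) of at
   least 5. Genes with zero pooled variance are untestable and carry p = 1.
2. *Guide similarity.* Absolute between-group mean difference > 10 RPKM and
   group fold change > 1.5 (a zero smaller mean counts as infinite fold).
   By default the higher group must match the guide's higher group
   (`direction = same-as-guide`); `either` is available. The guide's own
   contrast (8.53 RPKM, 1.69-fold) fails the first filter, so the guide
   normally enters through the DEG rule; no special-casing is applied.

**Network construction.** RPKM is square-root transformed; gene–gene Pearson
correlation; unsigned soft adjacency `a_ij = |cor_ij|^6`; topological
overlap `TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)`; average-linkage
clustering of `1 − TOM`. Branches are cut by a deterministic largest-gap
rule: candidate cut heights are the midpoints of substantial gaps (at least
a quarter of the widest gap) between consecutive merge heights above half
the maximum height, and the candidate producing the most branches of at
least `min_module_size = 30` genes wins (ties go to the widest gap, then
the lower cut). A fixed cut at 0.99 of the maximum merge height was tried
first and discarded: with modules of heterogeneous tightness the single
quantile either splits the tight modules or swallows the loose ones,
whereas the gap rule recovers planted modules reliably (acceptance checks
below). Unassigned genes are grey. Modules whose eigengene dissimilarity
`1 − cor(ME_p, ME_q)` falls below 0.25 are merged iteratively (closest pair
first, eigengenes recomputed per merge), and surviving modules are named by
the conventional colour sequence in decreasing size order.

**Module and gene statistics.** The module eigengene is the first principal
component of the module's gene-standardized expression, rescaled to unit
variance and sign-aligned to correlate non-negatively with the module mean
profile. Module–trait association is the Pearson correlation of eigengene
and trait with a two-sided t-transform p-value (n − 2 df); modules are
called significant at p < 0.001. Per gene: GS (correlation with malate),
MM/kME (correlation with the own module's eigengene; grey genes against the
grey pseudo-eigengene) and kTotal (adjacency row sum, diagonal excluded).

**Guide-calibrated selection.** MSAGs are all genes with `|GS| ≥ |GS_guide|`
(absolute values: the selection is invariant to trait sign). Intramodular
hubs are the top 12 genes by |MM| per significant module (ties by kTotal,
then gene ID). Subgroup connectivity reruns correlation → adjacency (same
β) on each genotype group's samples alone; each gene's kTotal changes are
classified purely by sign: `major` (up in *mama*, down in *Ma_*), `reverse`,
`down_both`, `up_both`, with `mixed` for deltas within 1e-9 of zero —
magnitudes are reported so users can impose their own cutoffs. Module-level
summaries report the |MM|–|GS| correlation per module and the whole-network
kTotal–|GS| r².

**Enrichment.** Terms are flat labels (GO-BP, GO-MF, MapMan bins; no graph
propagation). For each (namespace, module) pair every term is tested with
the exact hypergeometric tail, `p_over = P(X ≥ k)` and `p_under = P(X ≤ k)`,
BH-corrected within the pair; enrichment and depletion are reported
separately at `P_FDR < 0.05`. Backgrounds default to the namespace's
annotated universe and can be pinned per namespace.

**Regulator detection.** A simplified module-network scheme in the spirit of
two-way Bayesian clustering tools, fully specified here rather than
delegated: numerical equality with any external implementation is a
non-goal.

* *Preprocessing.* This stage log1p-transforms and row-standardizes
  expression: RPKM marginals are lognormal-like, and both the Gaussian
  mixture and the 1-D 2-means sample splits behave correctly on the log
  scale (on the raw scale the variance of the high-expression side inflates
  and skews every split).
* *Gene clustering.* A collapsed Gibbs sampler over a finite Bayesian
  mixture of Gaussians, independent conjugate normal–gamma cells per
  (cluster, sample): μ0 = 0, κ0 = 0.1, α0 = β0 = 1 on standardized data,
  symmetric Dirichlet(1) weights over K = 20 components. Assignments start
  from k-means++ and run 50 burn-in plus 100 recorded sweeps; the final
  sweep is the run's partition. Because single-gene moves cannot nucleate a
  new cluster (the empty-cluster prior predictive is far too broad), every
  fifth sweep applies greedy split proposals: a 2-means split of each
  cluster is accepted when the collapsed marginal likelihood plus the
  partition prior improves. Without these moves, early accidental merges of
  correlated modules are permanent.
* *Tight clusters.* Ten independent runs (seeds `seed + run`) are condensed
  by the pair co-clustering frequency graph (threshold 0.5); connected
  components with ≥ 10 genes, sorted by size, top 50 kept, numbered from 0.
* *Sample trees.* Each cluster's mean standardized profile is recursively
  split by optimal 1-D 2-means (max depth 3, minimum 4 samples, constant
  profiles stop); each node carries a Bayesian two-mean score (log marginal
  likelihood gain of two groups over one under the same normal–gamma
  prior).
* *P. scores.* A candidate's score against a tree sums, over internal
  nodes, `−log10 p` of the two-sided Welch t-test between the node's two
  sample sets, weighted by the node's sample fraction. The t-test makes the
  score invariant to affine rescaling of the candidate; the assignment
  pipeline feeds it the same log1p-standardized rows used for the trees.
  Candidates are user-supplied (a helper selects them by annotation terms,
  e.g. transcription factors / signal transducers, capped at 96); the
  regulator cutoff is the top 1 % of the pooled (candidate, cluster)
  scores, and all-equal pools flag nothing. Calibration scores 96 randomly
  drawn non-candidate genes identically and compares the two score sets
  with a two-sample z-test.

**Exports.** Network edges are gene pairs with `TOM > 0.10` (strict; the
threshold is configurable), written as a 3-column edge list and GraphML
with module colours as node attributes, plus per-gene edge counts. All
tables are tab-separated and re-readable; the run manifest records version,
seed, parameters and per-stage counts, and a rerun with the same inputs and
seed is bit-identical.

## Synthetic data generator

`acidnet.simulate` emulates the study conditions with planted ground truth.
Defaults are the study design: 17 + 12 samples, five modules of 60 genes,
300 background genes, guide contrast 8.53 RPKM / 1.69-fold.

* Each module m has a latent sample factor `f_m = s_m·c + u`, where `c` is
  the centred genotype contrast, `u` iid N(0, 1), and `s_m = ±2`
  (`group_separation`, alternating sign so some modules sit higher in each
  genotype — the downstream gene universe is genotype-associated by
  construction, as in the real study where all network genes are
  acidity-associated). Member genes are `exp(b_g + λ_m f_m + σ ε)` with
  per-gene lognormal baselines around `baseline_rpkm = 10`, one shared
  loading `λ_m ~ U(0.8, 1.2)` per module and `σ = noise_sd = 0.5`. The
  shared loading makes the noiseless limit exact (members are scalar
  multiples, pairwise correlation 1); per-gene individuality comes from
  baselines and noise. Values are non-negative without truncation.
* The trait is `malate = 5 + Σ coef_m f_m + 0.5 ε` (coefficients
  {module 0: +1.2, module 1: −0.5}), floored at 0; TA and pH are affine
  responses with noise. The guide gene sits in module 0 and receives its
  configured group means exactly in expectation via a mean-corrected
  lognormal multiplier that still tracks the module factor's within-group
  residual.
* One planted regulator per selected module (defaults: modules 0 and 2)
  expresses two states separated by 2 log units (own noise SD 0.25) across
  the binary sample split that best separates the module — computed as the
  2-means split of the module's realized log-standardized mean profile, so
  the planted truth is recoverable from the data rather than defined on the
  unobservable latent factor.
* Annotation plants one term per module covering ≥ 85 % of members, a
  transcription-factor-like term marking the planted regulators plus module
  decoys (96 candidates total, the study's panel size; decoys are module
  members because real candidate TFs are themselves network genes), and
  unstructured background terms.
* One integer seed drives a named `SeedSequence` stream per stage; the same
  config is bit-identical.

What the generator does **not** model: read-level sampling noise, gene
length effects in RPKM, between-replicate batch structure, correlated
annotation (ontology hierarchy), or any dependence of library size on
genotype. Passing recovery tests therefore demonstrates the pipeline's
correctness on idealized lognormal factor-model data, not performance on
real RNA-seq.

Within-group expression variance is a free parameter (no published
estimate); `noise_sd = 0.5` on the log scale with unit factor noise gives
within-module correlations ≈ 0.85–0.9, a realistic range for tight
co-expression modules. A known consequence of the lognormal marginals is a
power asymmetry of the proportions test: modules elevated in the smaller
group (12 samples) pair their larger variance with fewer samples and are
detected less often — an honest property of the test, visible in pipeline
runs as partial coverage of those modules.

## Numerical choices and degenerate inputs

* Zero-variance genes are dropped before correlation (with a warning); in
  subgroup networks they contribute zero connectivity instead.
* Correlations are clipped to [−1, 1]; correlation p-values use the
  t-transform with a guard at |r| = 1.
* Hub ranking uses |MM| (kME magnitude measures connectivity); ties break
  by kTotal then gene ID, so results are deterministic.
* The equality tolerance for kTotal-change classification is ε = 1e-9.
* Single-gene modules: the eigengene is the gene's standardized profile.
* A constant trait, an empty candidate set, and a sub-3-sample subgroup are
  rejected with descriptive errors; degenerate z-tests (both score sets
  constant) are reported as not computable rather than raising.

## Problem sizes used in the checks

The recovery checks run the full study design (5 × 60 modules, 300
background genes, 29 samples) for module/guide/MSAG recovery, and a
5 × 30 + 100 configuration for the regulator pipeline, whose ten Gibbs runs
per dataset dominate the cost; these sizes give stable pass/fail behaviour
across seeds while keeping a complete run in minutes. Statistical
calibration uses 10,000 null genes (type-I error), 1,000 random p-vectors
(BH), and exhaustive small-N hypergeometric enumeration.

## Known limitations

* The tree cut is a deterministic gap heuristic, not the reference dynamic
  hybrid cut; exact module boundaries can differ from WGCNA's on real data
  (planted-structure recovery, not reference equality, is the contract).
* The proportions test reimplements the moment-based weighted test from its
  published description; no claim of numerical identity with proprietary
  implementations is made.
* The regulator scheme captures the structure of module-network inference
  (tight clusters, sample partitions, probabilistic scores, top-percentile
  rule, random-control calibration) but is intentionally simpler than full
  module-network learners; scores are comparable within a run, not across
  tools.
* With two highly correlated planted modules the Gibbs sampler occasionally
  returns a partly merged partition in individual runs; the consensus step
  absorbs this in practice.
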
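# Methods

`coexnet` reconstructs an integrative multiscale coexpression-network
analysis for tumor cohorts: from a gene-by-sample expression matrix it
builds a planar filtered correlation network, detects a parent/child
hierarchy of coexpression modules across compactness scales, nominates
module hubs as candidate key drivers, prioritizes modules by survival
association, characterizes them with genetic/epigenetic/cell-type gene
signatures via Fisher's-exact enrichment, and assesses module
preservation in independent cohorts. This note records the model and
every place where the design was genuinely open.

## Expression QC chain

Stages are applied in a fixed order and tracked with a stage tag:

1. **log transform** — v → log2(v + 1) on RPKM-like nonnegative values.
2. **quantile normalization** — each sample column is mapped onto the
   across-sample mean of order statistics; ties within a column receive
   the mean of their target quantile values. On tie-free data the map is
   exactly idempotent. The tie rule necessarily breaks exact idempotence
   on tied data (tie-averaging changes a column's value multiset, so the
   pooled reference shifts on re-application); the effect is bounded by
   the within-tie spread of the reference and is irrelevant for
   continuous expression values.
3. **covariate residualization** — per gene, ordinary least squares on
   an intercept + one-hot categorical (batch, center, …) + numeric (age)
   design; the gene is replaced by its residuals plus its grand mean.
   Collinear design columns are dropped via rank-revealing QR. OLS is
   the minimal faithful choice for linear confounder removal; it
   preserves per-gene means and annihilates all linear covariate signal
   (verified to machine precision in the tests). Empirical-Bayes batch
   correction (ComBat-style) is deliberately out of scope.

Zero-variance genes are removed before the correlation screen, where
correlation is undefined.

## Planar filtered network (PFN)

All gene pairs are screened by Pearson correlation (Spearman available
by flag) with two-sided p-values from the t transform and
Benjamini–Hochberg control; pairs with q below the FDR cutoff (default
0.05) form the candidate list, ordered by |r| descending with
lexicographic tie-breaks so construction is fully deterministic.

The PFN is the planar maximally filtered graph (PMFG) of that list:
edges are inserted greedily in order, each kept iff the graph remains
planar. Planarity is decided combinatorially (left-right test) rather
than via a sphere embedding — the resulting edge set is the same object
and is testable. The implementation maintains the biconnected-block
structure incrementally: an inserted edge merges exactly the blocks on
the block-cut-tree path between its endpoints, so planarity is tested
on that merged block only, with two accelerations that do not change
the result — an O(1) rejection when the merged block would exceed its
3n − 6 planar edge budget, and a radius-2 local Kuratowski pre-check
(a nonplanar subgraph certifies nonplanarity). The output is verified
in the test suite against an independent brute-force oracle that
re-tests planarity by exhaustive K5/K3,3-subdivision search.

## Multiscale module hierarchy

Modules are found by recursive top-down splitting of the PFN, one tree
per compactness scale α (default grid {0.5, 1, 2}; α = 1 is the primary
scale). Connected components become children of the root outright. For
a connected module, candidate children come from seeded Louvain
community detection on |r| edge weights, post-processed by:

* **agglomeration** — communities that are not separable at scale α
  (cut weight ≥ (α/10) × the smaller internal weight) are merged,
  strongest cut first; this undoes the over-fine partitions Louvain
  produces on homogeneous planar regions, and
* **small-cluster merging** — clusters below the minimum module size
  (default 10) are absorbed by the sibling with the strongest
  connection.

A candidate child is accepted as a module iff it is *significantly
compact* — its weighted internal density (edge-weight sum / size)
exceeds that of 100 size-matched random connected subgraphs of the
parent (grown by seeded BFS) by at least 2/α null standard deviations —
or *quasi-disconnected* — internal weight > (10/α) × cut weight.
Accepted children recurse; genes of rejected candidates stay with the
parent, so leaves partition the clustered subset of each component.

This acceptance rule is the package's own derivation. Distance-based
k-medoids partitioning and fixed density-vs-size penalties were
prototyped and discarded: farthest-point seeding lands on peripheral
low-degree genes of real PFNs, and because planarity caps every
subgraph at 3n − 6 edges (and planar graphs always have O(√n)
separators), no fixed density or cut threshold can both split genuinely
modular regions and refuse to shatter homogeneous ones. The
null-calibrated rule does both: a homogeneous subgraph's children look
exactly like random connected subgraphs of it (z ≈ 0), while planted
blocks stand far above the null. α keeps its intended meaning — larger
α relaxes acceptance, giving smaller, more numerous modules
(empirically monotone on synthetic cohorts).

**Hubs / key drivers.** Within each module, a gene is a hub iff its
within-module degree exceeds the (1 − p_cut) quantile (default
p_cut = 0.05) of the degree-preserving rewiring null. Since rewiring
preserves every node's degree, the pooled null is exactly the module's
degree multiset; the quantile is therefore computed analytically — the
permutation parameters remain in the API, and the result equals the
sampling estimate at infinite permutations.

## Survival prioritization

A module's **eigen-gene** is the per-sample score vector of the first
principal component of its standardized gene block (SVD), sign-fixed to
correlate nonnegatively with the module's mean profile, which makes
results invariant to gene order.

Each module/stratum combination is tested two ways:

* **Cox proportional hazards** — univariate Newton–Raphson on the
  partial likelihood with Efron tie handling (the de-facto standard),
  convergence |Δβ| < 1e-8, two-sided Wald p. The covariate is
  standardized internally for stable steps and β is reported on the
  original scale. Monotone likelihood (perfect separation) is flagged
  and the p-value falls back to the likelihood-ratio test.
* **median-split logrank** — patients are stratified at the median
  eigen-gene value (ties to the low group, a deterministic rule) and
  compared by the standard two-group logrank chi-square (1 df).

The module prognostic score is MS_m = Σ_t −log10 p_t over the
configured family of tests; the default family is whole-cohort Cox +
logrank (T = 2), and strata (subtype, nodal status) × outcomes are
configuration-driven. No multiple-testing correction is applied inside
MS — the score sums raw p-values by definition; corrections appear only
in enrichment. Modules are ranked by MS descending with deterministic
tie-breaks (size, then id).

## Signature compendium

* **Differential expression** (tumor-vs-normal, subtype, mutant
  contrasts): a moderated Welch t — per-group variances are shrunk
  toward the all-gene median variance with a prior weight of 4
  pseudo-observations, and the Welch–Satterthwaite degrees of freedom
  gain 2×4 — followed by BH correction. Thresholds mirror common
  practice: q < 0.05 and linear fold change strictly > 1.2 (up) or
  < 1/1.2 (down), with fold change = 2^(mean log2 difference). This is
  a deliberately simple stand-in for a full empirical-Bayes moderated
  test; `SignaturePair.from_table` accepts externally computed per-gene
  (log-FC, q) tables from any DE engine. Null calibration (mean false
  discoveries ≤ nominal) and 2-fold power ≥ 90% are enforced in tests.
* **SMGs** — mutant-vs-wildtype differential expression per driver
  gene; the driver itself is excluded from its own signature; fewer
  than 3 samples in either group skips with a logged reason.
* **eMSGs** — Spearman correlation between methylation beta values and
  expression for an explicit (probe, gene) pair list: cis pairs from
  the probe annotation, trans pairs from a configurable candidate list
  (all-probes × all-genes is quadratic; the natural default is probes ×
  genes of prioritized modules). Bonferroni control is applied within
  the cis and trans families separately and genes are split by
  correlation sign. Spearman p-values use the Fisher z transform with
  variance 1.06/(n − 3): the Student-t transform was measured ~1.3×
  anticonservative at the deep-tail thresholds Bonferroni reaches over
  thousands of pairs, which would break the family-wise guarantee; the
  Fisher form is slightly conservative there (measured FWER ≈ 0.03 at
  nominal 0.05).
* **Hyper/hypo-methylation intersections** — HEMG = down-regulated ∩
  cis-hyper-methylated; HOMG = up-regulated ∩ cis-hypo-methylated.
* **Cell-score correlations** — per-gene Spearman against a per-sample
  score (stromal/immune estimates), BH-controlled, signed signatures.

## Enrichment

All enrichment is the one-sided hypergeometric over-representation test
(only enrichments are of interest); fold enrichment FE = k/(K·n/N).
Both Bonferroni and BH corrections are always reported across the full
test family — different downstream uses flag significance with
different corrections. The default background universe is the network
gene set, with the whole measured genome selectable. Note that
restricting the background (fixed k, K, n, smaller N) can only lower FE
and raise p. Perturbation signatures (e.g., from an overexpression
experiment) are projected onto a gene's k-layer network neighborhood
(default k = 5, the perturbed gene excluded) and tested the same way;
neighborhoods under 5 genes are flagged low-power.

## Module preservation

For each module, in the test cohort: **density** = mean |r| among the
module's genes; **connectivity** = Spearman correlation between genes'
intramodular connectivities (row sums of |r|) in reference vs test.
Both are z-scored against n_perm (≥ 100) random same-size gene sets
drawn from the shared genes; the summary is the mean of the two
z-scores (the median of two values), with a pseudo-counted permutation
p on the composite. A module is preserved iff z_summary ≥ 2 (the
conventional "at least moderate" threshold) and perm p < 0.05. Module
overlap between cohorts is reported as |a ∩ best-Jaccard-match| / |a| ×
100, relative to the query module.

## Synthetic cohorts

The generator emulates the data model the pipeline assumes; its
defaults are the study conditions used throughout the tests:

| parameter | default | meaning |
|---|---|---|
| genes × samples | 800 × 250 | desk-scale cohort |
| modules | 4 parents of 80, each 2 children of 40 | nested correlation blocks |
| r_parent / r_child | 0.35 / 0.65 | target mean within-block Pearson r |
| noise sd | 1.0 | iid log2-scale noise |
| survival | driver P1.C1, β = 1, h0 = 0.002/day, 30% censoring | proportional hazards on the driver factor |
| mutation | 30% carriers, 40 targets, log2 shift 1 | planted SMG effect |
| methylation | 30 cis probes at Spearman −0.7, 50 null probes | planted eMSGs |
| batch | 2 batches, shift sd 0.3 | recorded covariate |

Expression follows a nested factor model g = μ + u·λ_p·f_parent +
u·λ_c·f_child + σε with loadings solved in closed form from the
correlation targets (total variance T = σ²/(1 − r_child), λ_p² =
r_parent·T, λ_c² = (r_child − r_parent)·T) and a per-gene multiplier
u ~ U(0.8, 1.2) that creates the heterogeneous intramodular
connectivity (hub structure) real modules have; u is part of the gene's
identity and is shared by replicate cohorts, making the connectivity
component of preservation informative. Realized block correlations sit
within ±0.05 of targets at n ≥ 200 (the multiplier costs ≈ 0.02 of
attenuation). Survival times are exponential with hazard
h0·exp(β·z) on the standardized driver factor (the population quantity
the module eigen-gene estimates), with independent exponential
censoring whose rate is solved by bisection to hit the target event
fraction. Methylation betas are logistic squashes of Gaussians
anticorrelated with their gene; Spearman is invariant to the monotone
squash, so the planted rank correlation survives, with the latent
Pearson level set by r = 2·sin(π·ρ_s/6). Raw expression is exported as
2^g − 1 (clipped at 0), so the QC chain applies from the top.

What the generator does **not** emulate: negative-binomial count noise,
copy-number events, non-proportional hazards, batch-by-module
interactions, and annotation errors. Passing tests therefore
demonstrate correctness of the machinery and calibration under the
stated model, not performance on real tumor cohorts.

A replicate cohort redraws samples from the same loadings (module
structure preserved); the reshuffle option permutes the gene-to-module
assignment as a structure-destroyed negative control. The truth
manifest (modules, loadings, multipliers, survival/mutation/methylation
plants, batch labels) is sufficient to score every recovery experiment.

## Numerical choices and degenerate inputs

* All orderings that affect output are fully specified (|r| descending
  with lexicographic tie-breaks; MS descending with size-then-id
  tie-breaks); every stochastic step takes an explicit seed, and the
  whole pipeline is byte-reproducible for a fixed seed.
* Cox: step clipping at |Δβ| ≤ 2 with step halving; zero-variance
  covariates are an error; < 2 events is an error.
* Logrank: a split with zero variance in the O−E statistic returns
  statistic 0, p 1; no events at all is an error.
* Eigen-genes need ≥ 3 non-constant module genes.
* Enrichment with an empty query or target after background restriction
  returns k = 0, FE = 0, p = 1, flagged.
* p-values are clamped into (0, 1] — −log10 p in MS is always finite.
* Preservation skips modules with < 5 genes in the test cohort and
  flags modules with < 50% of genes shared.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` run the full pipeline on the
800 × 250 preset (10 and 3 seeded cohorts respectively) and use a
240-gene/200-sample cohort with the same nested 4 × 2 module design for
the experiments that need many repetitions (prioritization over 100
seeds, preservation controls, determinism), plus purpose-built
instances for oracle comparisons (8-node graphs for the planarity
oracle; all 2×2 margins with N ≤ 40 for the hypergeometric oracle) and
direct simulations for statistical calibration (Cox null at n = 500,
β recovery at n = 400, DE/eMSG nulls at 500–1000 features). These sizes
were chosen so each property is tested at meaningful power on one CPU.

## Known limitations

* The multiscale clustering and preservation statistics are documented
  re-derivations, not reproductions of any published implementation;
  module boundaries and preservation calls on real data will differ
  from other tools in detail.
* The moderated Welch test is not an empirical-Bayes DE engine; for
  publication-grade DE, import external results via the table hook.
* The trans-eMSG universe must be chosen by the user; genome-wide
  trans testing is quadratic and left off by default.
* Quantile normalization's tie rule trades exact idempotence on tied
  data for well-defined tie handling.
* MS sums raw p-values across a configured test family; families of
  different sizes are not comparable without normalization.
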
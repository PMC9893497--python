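# Methods

## Differential expression model

Counts are modelled as negative binomial, `y_gs ~ NB(mean μ_gs, var μ_gs +
φ μ_gs²)`, with one common dispersion φ per two-group comparison. The
comparison cohort for stage *k* pools that stage's tumour samples with all
normal samples; with four stages, every normal sample is reused four
times. This matches the staged-cohort convention the pipeline targets and
means the four stage-wise tests are *not* independent of one another —
downstream set comparisons treat them as four views of one cohort, not as
four experiments.

### Normalization

CPM filtering keeps genes with CPM above `cpm_threshold` (default 1) in
at least `min_samples` samples (default: the smaller group size). TMM
factors follow the classic recipe: reference = sample whose 75th
count-proportion percentile is closest to the mean of those percentiles;
per sample, gene-wise M-values (log₂ ratio of library proportions vs the
reference) are trimmed at 30% by M-rank and 5% by abundance (A) rank and
averaged with inverse asymptotic-binomial-variance weights; factors are
rescaled to geometric mean 1. Ranks use midranks for ties. A sample whose
trimmed M-values are all below 1e-6 in magnitude gets factor 1. The
implementation reproduces the reference R implementation to ~7
significant digits on fixtures (frozen oracle values in the test suite).

### Dispersion

φ is estimated by conditional maximum likelihood on quantile-adjusted
pseudo-counts: counts are mapped from their fitted per-sample NB
distribution (per-gene group means fit by Newton iteration on the
intercept-only log-link model with library-size offsets; hard error with
the iteration count if 50 steps do not converge) to a common
geometric-mean library size, averaging a normal and a gamma tail
approximation of the NB quantile map. With equal library sizes the group
sum is sufficient, so the conditional log-likelihood per gene and group is
`Σ_j lgamma(y_j + 1/φ) + lgamma(n/φ) − lgamma(z + n/φ) − n·lgamma(1/φ)`.
Because the pseudo-count map itself depends on φ, mapping and maximization
alternate twice (starting at φ = 0.01). Maximization runs on a 25-point
log grid over [1e-4, 10] with bounded scalar refinement between the
bracketing grid points; if the maximum sits at the lower grid boundary
the estimate is reported as exactly 0 (the Poisson limit).

### Exact test

Conditional on a gene's rounded pseudo-count total `z`, the tumour-group
sum is beta-binomial with weights `n_t/φ` and `n_c/φ` (the Gamma–Poisson
mixture makes this exact for equal library sizes), degenerating to
binomial(`z`, `n_t/n`) at φ = 0. The two-sided p-value sums the
probabilities of all outcomes no more likely than the observed one;
"no more likely" uses a 1e-12 relative tie tolerance, and the pmf is
normalized in log space, so p ∈ [0, 1] by construction. Totals above
2·10⁶ (never reached at the shipped simulation scale) fall back to a
normal approximation with the beta-binomial overdispersion factor,
doubling the smaller tail. log₂ fold change is
`log2((s_t/n_t + c) / (s_c/n_c + c))` with a flat prior count c = 0.125
to avoid infinities; average abundance is reported as log₂ CPM of the
damped gene total at the common library size.

### Calling

BH step-up adjustment (`fdr_i = min_{j ≥ rank(i)} m·p_(j)/j`, capped at
1) is one shared function used verbatim by both the DE and the enrichment
module. DEGs require strict `fdr < 0.05` and non-strict `|log₂FC| ≥ 1`;
"≥ 1" is applied to the magnitude since both directions are retained
downstream.

## Network construction

The fold-change/confidence filter keeps a DEG only if `|log₂FC| > 1.5`
(strict) *and* it has an interaction with confidence `> 0.75` (strict)
whose other endpoint also passes the fold-change cut — an isolated strong
DEG carries no module signal. The per-stage FI graph is the induced
subgraph on the filtered genes at the same strict confidence cut, keeping
isolated nodes. The PPI graph uses a *non-strict* score ≥ 0.75: the two
thresholds are stated differently in the workflow this package
implements ("> 0.75" vs "criterion was 0.75"), and both are config
options. Edge lists deduplicate reversed pairs keeping the maximum
confidence (a reliability score: best evidence wins) and drop self-loops,
since all downstream statistics are defined on simple graphs.

## MCL

Defaults: inflation 2.0, expansion 2, entry pruning below 1e-5 with
column renormalization, convergence when successive matrices differ by
less than 1e-8 in max-norm, 200 iterations maximum (non-convergence
returns the current partition with a logged warning). Self-loops are set
to each node's maximum incident edge weight (1 for isolated nodes), the
standard regularization against parity oscillation; edge confidences are
used as weights rather than binarized. Clusters are read off the limit
matrix's attractor rows; overlapping attractor systems (rare) are merged
so the output is a partition. Module order is deterministic (decreasing
size, then lexicographically smallest member), making results invariant
to node input order. Module selection requires ≥ 5 genes *and* a
connected induced subgraph.

## Evolution network

Intra-stage edge weights count stage-graph edges crossing between two
retained modules; within-module edge counts are node attributes, not
self-edges, so the conservation law *crossing + internal = total edges*
holds exactly and is tested exhaustively. Adjacency is fixed to (I,II),
(II,III), (III,IV); inter-stage weights are plain intersection sizes with
`min_overlap = 1` (no cutoff is imposed — edge weights carry the
information, and consumers can threshold by percentile). Intra-stage
cluster edges are computed on the retained modules over the *full* stage
FI graph. Component extraction breaks size ties by smallest
stage-qualified node id and reports whether all four stages are present.

## Enrichment

Upper-tail hypergeometric `p = P(X ≥ k)` for overlap k between a module
of n genes and a pathway of K genes in a universe of N. The default
universe is the measured (post-CPM-filter) genes that appear in at least
one pathway, the convention of annotation services; modules are
intersected with the universe before testing (a module gene in no pathway
cannot contribute to any overlap), and `universe_mode="all_measured"`
switches to the full measured background. The stage-level summary takes
the minimum module-level p per pathway — the only deterministic reduction
consistent with "significant somewhere in this stage" — and the heatmap
export orders rows/columns by average-linkage hierarchical clustering of
Euclidean distances between −log₁₀ p profiles (untested cells treated as
p = 1 for ordering only; they stay missing in the matrix).

## Hubs

Ranking is by degree alone; unnormalized betweenness (each unordered pair
counted once, endpoints excluded) is reported and used only to break
degree ties, with gene id as the final tie-break for determinism. The hub
subnetwork keeps each hub's full-graph degree as a node attribute for
colour mapping. The PPI gene list defaults to the union of per-stage
filtered DEGs; `ppi_gene_source="intersection"` restricts it to genes
differentially expressed in all four stages.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical skeleton the analysis assumes:

- **Design.** Group sizes default to the reference staging cohort
  (41 normals, 45/109/80/37 tumours) so comparison cohorts are 86/150/121/78.
- **Counts.** `μ_gs = L_s · exp(b_g + Δ_gs)` with baseline log-means
  uniform on ln 8 … ln 400 (mean counts ~8–400, a realistic expressed-gene
  range after CPM filtering), library scales log-uniform on ×0.5–×2 (so
  TMM has real work to do), and NB dispersion φ = 0.1 (typical bulk
  RNA-seq). Planted fold changes are ±2 on the log₂ scale — strong,
  deliberately: the pipeline's module logic is the object under test, not
  borderline DE power.
- **Planted structure.** 5% of genes are DE per stage. Genes of the 8
  planted modules (8–12 genes each) are DE in *all* stages with a
  per-gene direction fixed once (hence zero contra-regulated genes, a
  property the staged analysis expects); the remaining per-stage quota is
  stage-exclusive. Within-module edges appear with probability 0.9 and
  confidence in [0.8, 1.0]; all other pairs with probability 0.002 and
  confidence below 0.75, so the confidence filter provably strips
  cross-module noise in the planted model. The first 8 pathways draw 90%
  of their members from their aligned module.

Real data differ in ways the generator does not model: gene-length and GC
effects, batch structure, dispersion that varies with abundance
(tagwise/trended), modules that overlap or change membership gradually,
and interaction confidences correlated with expression. Passing tests
therefore demonstrate correctness of the algorithms and the end-to-end
plumbing under the stated model — not that any particular biological
cohort will yield clean stage-spanning modules.

## Problem sizes and numerical choices

The shipped study design is 2,000 genes × 312 samples, which exercises
every code path while keeping a full pipeline run in seconds and the
whole validation suite under a minute; null-calibration checks use 2,000
genes at 10 vs 10 samples and φ = 0.1. Other fixed numerics: exact-test
tie tolerance 1e-12 (relative); TMM degenerate-case cutoff 1e-6 on
|M|; Newton tolerance 1e-10 for group means; dispersion grid 1e-4…10
(25 points, log-spaced) with 1e-6 refinement tolerance; MCL pruning
1e-5 and convergence 1e-8. All randomness flows from a single integer
seed through one `numpy` generator per artifact (seed, seed+1, seed+2 for
counts, interactions, gene sets); the analysis branch is deterministic,
so pipeline outputs are byte-identical across runs at a fixed config.

## Known limitations

- Only the classic common-dispersion exact test is provided; no
  GLM/quasi-likelihood path, tagwise dispersion, or batch covariates.
- The beta-binomial conditional is exact only after library-size
  equalization; the pseudo-count map is an approximation shared with the
  reference implementation of this workflow.
- MCL is the only clustering offered, and its result is read as a hard
  partition (overlapping attractor systems are merged).
- Enrichment assumes independent gene sampling under the null; gene-gene
  correlation within modules makes nominal p-values anti-conservative on
  real data, which is why the planted-recovery tests check ranking and
  thresholded recovery rather than p-value calibration.
- Identifier semantics are opaque strings end to end; no symbol mapping.
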
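# Methods

`tonsilflow` re-implements, as a tested pipeline, a tonsillar B-cell
scRNA-seq analysis: quality control and normalization, graph clustering
with covariate-adjusted marker detection, regulon (TF → target network)
inference with per-cell activity scoring, and principal-curve pseudotime
with spline modeling of gene expression and regulon activity along the
germinal-center–to–antibody-secreting-cell (GC→ASC) axis.  Every stage is
exercised end-to-end against a synthetic generator with planted ground
truth, so the claims the tests make are claims about method behavior
under a known model, not about any particular tissue sample.

## The synthetic cohort

The generator (`tonsilflow.simulate`) draws a multi-donor cohort from a
negative-binomial model.  For cell *c* and gene *g*,

    counts_gc ~ NB(mu_gc, theta),   Var = mu + mu^2/theta
    mu_gc = L_c * softmax_g(eta_gc)
    eta_gc = log base_g + state effect + donor effect
             + sum_t activity_t(c) * beta * w_gt + continuum effect

with log-normal library sizes `L_c`.  The NB uses the mean/dispersion
parameterization above (`nb_dispersion` = θ, default 10, moderate
overdispersion; θ = ∞ is the exact Poisson limit).  Defaults emulate the
study design the pipeline targets: 3 donors × 700 cells, 1500 genes, 18
discrete states, donor effect SD 0.2 on the log scale.

Structure planted in the cohort, and what recovers it:

- **Discrete states.** Each state up-regulates ~8% of generic genes with
  ln-fold-changes ~ N(1.2, 0.4).  PCA + SNN + Louvain recovers these
  (adjusted Rand index is the measure).
- **GC→ASC continuum.** Cells of the designated branch states carry a
  latent time t ~ U[0,1]; the state label is the quartile bin of t, so the
  branch's cluster path is ordered.  "Rising" and "falling" genes follow
  scaled logistic curves in t (midpoint U[0.3, 0.7], steepness
  U[0.08, 0.15], amplitude ≈ 2 on the ln scale).  PRDM1 is an exception:
  as a terminal ASC marker it switches late and sharply (midpoint 0.85),
  which is what lets the partition rule separate GC from ASC clusters.
- **Regulons.** Every TF has exactly `targets_per_tf` targets: a shared
  core of `round(overlap × k)` genes common to all TFs plus private
  disjoint remainders, so pairwise overlap is exact by construction.  TF
  activities are state-specific indicators or logistic functions of t;
  targets (and the TF's own transcript) shift with activity, which is the
  signal the tree-ensemble GRN step and the activity splines recover.
- **Chemokine scenario.** An activated state co-expressing CCL4 and CCL3
  via exactly three planted TFs, which the dual-targeting scan must
  return exactly.
- **Artifacts.** Four planted QC-failure classes: low-gene cells
  (library ~ U[80, 150], guaranteeing < 200 detected genes),
  high-mitochondrial (block boosted to 10–25% of counts, threshold 5%),
  high-dissociation (6–15%, threshold 4%), and T-cell contaminants
  (Poisson(8)+1 counts on CD3D/IL32/CD2).  Designated gene blocks
  (prefix `MT-`, prefix `DSG`, the named markers) let the QC stage's
  gene-list inputs point at the synthetic universe.

What the generator does **not** emulate: ambient RNA, doublets, UMI
collisions, batch effects beyond a per-donor log-scale shift, and any
realistic gene–gene correlation beyond the planted programs.  Passing
tests therefore demonstrate correctness of the machinery under the
stated model, not robustness to all real-data pathologies.

## QC and normalization

Filters (defaults, order: cells first, then genes): ≥ 200 detected genes
per cell; mito fraction > 5%, dissociation fraction > 4% or > 40,000
detected features removed (strict inequalities); cells detecting ≥ 2 of
{CD3D, IL32, CD2} removed as T-cell contaminants; then genes detected in
< 3 surviving cells removed.  The 40,000-feature cutoff is interpreted as
detected-feature count (configurable).  Filtering is idempotent.

Normalization produces clipped Pearson residuals under a regularized NB
model: the per-gene mean is `mu_gc = depth_c × pi_g` (the closed-form fit
of a log-link regression on log total counts with unit slope); the
per-gene dispersion is a moment estimate regularized by Gaussian-kernel
smoothing of log θ over log gene mean with Silverman's bandwidth;
residuals are clipped at ±√n_cells.  Residuals of overdispersed genes
are approximately invariant to jointly rescaling counts and depths; the
invariance is exact only in the dispersion-dominated limit, and the test
tolerance (mean |Δ| < 0.05 after doubling) documents it.

Variable genes: top 3000 per donor by residual variance, union over
donors, gene-ID tie-break.  Donor integration is deliberately simple:
per-donor centering and rescaling of each variable gene's residuals to
the pooled SD.  This removes additive donor effects exactly and is the
package's substitute for anchor-based integration, which is a large
external algorithm orthogonal to what is being tested; it is the one
stage that does not attempt to match its full-scale counterpart.

## Clustering, markers, activities

PCA (35 components, full SVD) on variable genes excluding Ig light-chain
prefixes (IGKC/IGLC); component signs fixed by the largest-|loading|
gene so runs are bit-reproducible.  The SNN graph uses the kNN (k = 30,
euclidean) neighbor sets including self; edge weight = Jaccard overlap;
edges below 1/15 trimmed.  Louvain (multilevel modularity, resolution
1.3) runs with a seeded RNG and first-occurrence label canonicalization.
Note the resolution-γ null model fragments small cliques (a clique stays
whole only for n < γ/(γ−1) ≈ 4.3 at γ = 1.3); this is inherent to the
RB modularity scaling, not an implementation artifact.

Markers: one-vs-all logistic regression of cluster membership on each
gene's log-normalized expression with donor indicator covariates; LR
statistic vs the donor-only null ~ χ²(1); BH within cluster; markers
need p_adj < 0.01 and log2FC > 0.3, where log2FC compares expm1'd
log-normalized means with pseudocount 1.  The IRLS is ridge-stabilized
with coefficients capped at ±30 so perfectly separating genes yield a
finite saturated fit (the LR statistic is unaffected at that magnitude).

Gene-set and regulon activity is a ranked-recovery AUC: per cell, genes
are ranked by decreasing count with deterministic gene-ID tie-break (the
published algorithm randomizes ties; determinism was preferred and is a
documented deviation); the score is the area under the set's recovery
curve within the top 5% of the ranking, normalized by the maximum
achievable area, hence in [0, 1] and invariant to monotone transforms of
the counts.  Differential activity per cluster is a one-vs-rest Wilcoxon
rank-sum test with discrimination AUC = U/(n₁n₂); a set is enriched when
AUC > 0.85 (one-sided, enrichment only) and the BH-adjusted p < 0.05.

The non-GC/GC/ASC partition binarizes each of CCR7, CD38, PRDM1 per
cluster against the median of cluster means (scale-free, configurable):
CCR7⁺ → non-GC (taking precedence, ambiguity flagged), CCR7⁻CD38⁺PRDM1⁻
→ GC, CCR7⁻CD38⁺PRDM1⁺ → ASC, anything else non-GC with a warning.
The median split necessarily dichotomizes near-zero cluster means
arbitrarily when one marker is absent from most clusters; with planted
bimodal markers the calls are correct where it matters.

## Regulons

Per target gene, an extra-trees regression (30 trees, depth 5, seeded)
of log-normalized expression on all TF expressions; normalized feature
importances ≥ 0.01 become edge weights.  Pruning intersects edges with a
TF→target prior table — the stand-in for motif-based pruning, accepting
the synthetic truth, a user's motif-database export, or nothing (top-50
per TF by weight as fallback).  Motif scanning itself is out of scope.
Hypergeometric over-representation uses the upper tail P(X ≥ k) with BH
within each query set; the universe defaults to the QC-surviving genes
(the choice is configurable since full-scale universes are debatable).

## Trajectory and splines

The principal curve is Hastie–Stuetzle with a predefined cluster path:
initialize with the polyline through path-cluster centroids, then
iterate {project cells onto the densified polyline; sort by arc length;
smooth each embedding coordinate against arc length with a GCV-tuned
cubic smoothing spline (local-linear fallback for tiny lineages);
re-parameterize by arc length}.  Convergence is declared when the mean
squared projection distance changes by less than tol × total embedding
variance (scale-free; the GCV smoother re-tunes each pass and leaves a
small jitter floor that an absolute criterion would never cross).
Orientation is fixed by the root cluster (lower mean arc length than the
terminus).  Off-lineage cells are excluded rather than soft-weighted — a
simplification of the original cell-weight scheme.  Coordinate-wise
smoothing makes pseudotime only approximately invariant under rotation
of the embedding (rank correlation ≳ 0.98 in tests).

Association testing is one family-parameterized implementation: the
mean is modeled on a cubic B-spline basis in pseudotime with 3 interior
knots at the t-quantiles {0.25, 0.5, 0.75} (the "knots = 3" reading; the
exact bases of the upstream R packages are not reproduced), and the
statistic is the Wald χ² that all non-intercept spline coefficients
vanish.  Genes use an NB GLM with log library-size offset and a
two-step dispersion: Poisson fit, moment estimate of the NB2 α from
Pearson residuals, NB refit.  Regulon activities use the Gaussian
family.  Given identical Gaussian inputs the two entry points return
identical statistics (tested).  Thresholds: genes flagged at unadjusted
p < 0.01 (the stricter of the two readings the source material permits;
the adjusted variant is exposed as a flag), regulons at BH-adjusted
p < 1e-5 (a 1e-6 variant also appears in the source's figure legend;
the Methods/Statistics value is the default and the flag exposes the
other — the discrepancy is documented rather than resolved).  Genes
detected in < 5% of lineage cells are excluded and counted.

Fitted means are evaluated on a 100-point equispaced grid, z-scored per
feature, and clustered with complete-linkage agglomeration on Manhattan
distances, cut at 6 clusters.  Complete linkage is a choice (the
linkage was unstated upstream); it is compact and deterministic.

## Problem sizes and numerical conventions

Tests and the acceptance script run at desk scale as the package's own
study conditions: 3 × 700 cells × 1500 genes for the full cohort, 600
cells / 6 states for the clustering benchmark, ~450 continuum cells for
trajectory work, 2000 null genes × 1000 cells for calibration.  Seeds
derive from a single global seed via `SeedSequence([seed, stage])`, all
below 2³¹.  Empty gene sets are dropped with warnings; zero-count cells
get zero QC fractions with a warning; constant features get AUC 0.5 /
p = 1; non-converged fits return p = NA and are logged, never silently
dropped.

## Known limitations

- The donor integration removes additive per-gene donor effects only;
  nonlinear batch structure would survive it.
- GRN inference is correlational; strongly co-activated TFs (the three
  chemokine TFs share one activity pattern) split importance and are
  distinguished only by the pruning prior.
- The NB α moment estimator can be noisy for very low-expression genes;
  the detection prefilter bounds the damage.
- Single predefined lineage only: no branch-point detection, no
  multi-lineage trees, no RNA velocity.
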
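# Methods

This note documents the models implemented in `phylomorph`, the choices
made where the methodology was genuinely open, and what the synthetic-data
tests do and do not demonstrate.

## Procrustes superimposition

`gpa_align` performs full generalized Procrustes analysis: configurations
are centered, scaled to unit centroid size, and rotated by least squares to
an iteratively updated consensus (convergence when the consensus moves less
than `tol = 1e-10` in summed squared coordinates, or after `max_iter = 100`
iterations; the residual sum of squares is non-increasing across
iterations and is recorded in `AlignedShapes.ss_history`).  Choices:

* **Reflections are never permitted** in the optimal rotation (determinant
  forced to +1): biological specimens have handedness.
* **No tangent-space projection by default.** Downstream Euclidean
  operations assume small shape variation; the synthetic generator keeps
  deviations at a few percent of centroid size, where the difference is
  negligible.
* **Consensus aligned to its principal axes** at the end so output
  orientation is reproducible run to run.
* **Species means are averages of jointly aligned specimens** (a single
  GPA over all specimens, then within-species means, re-centered but not
  re-superimposed — means of unit-size centered shapes are already centered
  to numerical precision).
* No sliding semilandmarks and no missing-landmark estimation; records
  with missing coordinates are rejected at load time.

## Ordination

PCA is the SVD of the centered species-mean matrix (covariance denominator
n−1), with a deterministic sign convention (largest-magnitude loading of
each axis positive).  Axis retention uses the broken-stick rule with
*strict* inequality, stopping at the first non-significant axis, which
prevents non-contiguous "significant" sets.  Phylomorphospace internal
nodes are GLS ancestral estimates under Brownian motion (below), and no
phylogenetic correction is applied to the PCA itself so that convergence
remains visible in the ordination.

## Brownian-motion machinery

For a rooted tree with branch lengths, the BM tip covariance is
C_ij = depth of MRCA(i, j).  The phylogenetic (GLS) mean is
â = (1ᵀC⁻¹1)⁻¹1ᵀC⁻¹Y, ancestral states are the conditional expectations
â + C_node,tips C⁻¹ (Y − â) (equal to the GLS/ML reconstruction; the root
estimate equals â), and phylogenetic correction is
U = C^{−1/2}(Y − 1âᵀ), computed via eigendecomposition with eigenvalues
floored at 1e-12 — trees with near-zero terminal branches otherwise make
C numerically singular.  The API marks transformed arrays and refuses to
transform twice, since double correction is statistically meaningless.

K_mult is the ratio of the ordinary to the phylogenetically corrected mean
squared deviation from â (traces over all trait dimensions), divided by its
BM expectation (tr C − n/(1ᵀC⁻¹1))/(n−1), so K ≈ 1 under single-rate BM on
the given tree.  All permutation p-values in the package use
(b + 1)/(m + 1), which can never return zero; the default permutation
count is 1000.

## Modularity and integration

The covariance ratio for two modules is
CR = √( tr(S₁₂S₂₁) / √( tr(S₁₁°S₁₁°) · tr(S₂₂°S₂₂°) ) ) with within-module
diagonals zeroed; for more than two modules the statistic is the mean of
the pairwise CRs.  CR = 1 is the no-modularity anchor, lower values mean
relatively less between-module covariation.  The permutation null
**reassigns landmarks to modules** (preserving module sizes) because the
hypothesis under test is the partition, not the species sampling; p-values
are left-tailed (#null ≤ observed).

For model comparison the effect size of each hypothesis is standardized
against a **common null pooled across all hypotheses**.  A per-model null
would systematically reward coarse partitions — their null distributions
are much tighter, inflating |Z| regardless of fit — whereas the pooled
standardization makes the ranking coincide with the observed-CR ordering
while still giving an interpretable scale.  The one-module hypothesis
cannot yield a CR and anchors the "no modularity" end with an empty
statistic; ties are reported, not broken.

Integration uses two-block PLS on the (transformed, centered) module
blocks: rPLS is the correlation of the first pair of singular-variate
scores of the between-block covariance, averaged over module pairs for
>2 modules.  Nulls permute species rows of one block per pair.  Summary
networks label rPLS ≥ 0.75 as high integration and CR ≥ 1.00 as high
covariation; both cut-offs are configurable and purely descriptive.

EMMLi-style selection builds the landmark × landmark congruence-coefficient
matrix (inner-product correlation of the d-vector deviations, the standard
correlation for landmark data) and pools each hypothesis's unique
landmark-pair correlations: one ρ per within-module set and one per module
pair.  The likelihood is the Fisher-z normal approximation at the given
sample size; AICc uses K = number of distinct ρ parameters + 1 and the
number of species as the sample size, and models the sample size cannot
support (n ≤ K + 1) are flagged unfit and excluded from the AICc weights.
Pairwise p-values are reported raw; an optional Benjamini–Hochberg column
can be derived from the pairwise tables but is never used for headline
results.

The shipped 7-region landmark map (33 landmarks: mouth 6, neurocranium 10,
opercula 4, pectoral+dorsal 5, pelvic 4, anal 2, caudal 2) and the
ten-model battery are labelled reconstructions: the 1-, 2- (head vs
postcranium), 3- (head/midbody/tail), 4- (mouth | head | fins | tail) and
7-module models follow the motivating analysis, and five further merges of
the seven regions complete the battery.

## Evolutionary rates

The per-module rate is σ²_m = Σ (transformed deviations over the module's
coordinates)² / (n_species × module dimension); the statistic is
max σ²/min σ² and the null replicates single-rate BM datasets on the tree
at the pooled rate.  Doubling all branch lengths halves every σ² and
leaves the ratio unchanged.

Multirate BM places a log rate at every node; an edge's rate is the mean
of its endpoint rates, the tip likelihood is the profiled-mean multivariate
normal under the resulting covariance, and the penalty is λ times the BM
log-density of the node log-rates on the same tree.  The BM variance of
the rate process is **fixed at 1 per unit branch length**: the motivating
description leaves it unstated, and estimating it jointly makes the
penalty degenerate (a constant rate profile has unbounded density as that
variance shrinks).  With this convention λ → ∞ recovers the single-rate
maximum-likelihood estimate, which is also the optimizer's start point
(L-BFGS-B, ftol 1e-8, 500 iterations).  Rates for ordination axes are
fitted per axis independently.

## Convergence and disparity

C metrics: D_tip is the maximum pairwise distance among the focal tips and
that pair defines the two lineages; D_max is the maximum distance between
any two (ancestral or tip) points along the lineages since their
divergence.  C1 = 1 − D_tip/D_max, C2 = D_max − D_tip, C3 divides C2 by
the summed evolution along the two lineages, C4 by the summed evolution in
the clade spanned by the focal taxa.  P-values simulate BM with the rate
matrix estimated from the data ((Y−â)ᵀC⁻¹(Y−â)/n) and count simulations
with metric ≥ observed.

The ellipse-crossing count uses the **minimal-area enclosing ellipse** of
the focal tips (Khachiyan's algorithm; the original construction is not
described, so the area is reported but treated as descriptive only).
Lineages are root-to-tip polylines through projected ancestral positions;
counts are reported both with and without the focal lineages since the
original counting rule is ambiguous.  Collinear focal sets raise an error
suggesting a buffer radius.

Disparity-through-time interpolates every branch alive at each of 31
evenly spaced slices between its endpoints' positions and reports the
**mean squared pairwise Euclidean distance** among those points.  The
motivating description says only "distance-based"; the mean-squared form is
scale-stable across lineage counts, which means absolute disparity
magnitudes from other implementations are not comparable — only profile
shape, ordering and burst structure are.  At the final slice the profile
equals the direct tip disparity exactly.  A burst is a between-slice
increase strictly greater than the threshold (default 10).

## Synthetic data

`simulate_modular_shapes` evolves flattened landmark deviations by
multivariate BM along the tree: unit-diagonal block correlation R
(within-module ρ_w, between ρ_b, positive-definiteness checked at
construction), per-module rate multipliers applied as √rate row/column
scaling, increments ~ N(0, t_edge · R_scaled).  Deviations are added to a
fixed non-degenerate base shape (regular polygon in 2-D, spiral in 3-D)
and specimens add isotropic digitising noise.

Defaults mirror the motivating study: 71 species, 3 specimens per species,
33 landmarks in 3-D over the seven regions, ρ_w = 0.7, ρ_b = 0.1, noise
sd 2% of centroid size, BM scale 5% of centroid size per unit tree depth
(kept small so shapes stay in the near-tangent regime).  Pure-birth trees
are rescaled to unit depth.

What passing tests show: the estimators are calibrated and powerful under
block-structured BM with isotropic digitising noise.  What they do not
show: robustness to allometry, to measurement error correlated across
landmarks (e.g. digitising whole regions inconsistently), to
non-ultrametric or misspecified trees, or to strongly non-BM evolution
(OU, early-burst) — none of which the generator emulates.

## Problem sizes in the test suite

The statistical acceptance tests run at the sizes the guarantees are
stated for: 200 null datasets (CR calibration and each type-I check,
40 species), 500 BM simulations (K_mult calibration, 30 species), 100
recovery runs (model selection at the 71-species default; rate ratio at 50
species).  Unit tests for the slower penalized-likelihood optimizer use
12–15 tip trees, where its behaviour (single-rate limit, smoothing
monotonicity) is already unambiguous.

## Known limitations

* EMMLi's Fisher-z likelihood treats landmark-pair correlations as
  independent observations; it inherits the known tendency to favour
  richly parametrized models, which is why model choice is cross-checked
  with the CR ranking.
* The CR model ranking compares observed CRs on a pooled null; it does not
  provide a formal test between two specific hypotheses.
* Multirate BM uses numerical gradients; trees beyond a few hundred nodes
  will be slow.
* `convnum_ellipse` requires exactly two morphospace axes and at least
  three focal taxa in general position.
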
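# Methods

`protraj` reconstructs a branching tumor-progression model from a single
cross-sectional cohort of bulk expression profiles.  Each tumor is treated
as a snapshot of a continuous disease process; with enough snapshots the
process itself — a tree rooted at normal tissue, with paths toward
alternative malignant endpoints — can be recovered and then interrogated
statistically.  This note records the models, the numerical choices, and
what the synthetic validation does and does not establish.

## 1. Disease-gene selection (large-margin local learning)

Let (x_n, y_n) be expression vectors with ordinal grade-group labels.  For
a non-negative feature-weight vector w, the margin of sample n is

    rho_n(w) = d(x_n, NM(x_n) | w) − d(x_n, NH(x_n) | w) = wᵀ z_n,

where NM/NH are the nearest miss/hit under the weighted Manhattan distance
and z_n = |x_n − NM| − |x_n − NH|.  Genes are scored by minimizing the
l1-regularized logistic margin loss

    (1/N) Σ_n log(1 + exp(−wᵀ z̄_n)) + λ‖w‖₁,   w ≥ 0.

Because nearest neighbors depend on w, an EM scheme is used: the E-step
replaces z_n by its expectation z̄_n under neighbor probabilities from an
Epanechnikov kernel (k(u) = max(0, 1 − u²)) over the 5 nearest same-class
and different-class candidates, with the bandwidth set to the 5th-nearest
candidate distance; the M-step takes a few projected proximal-gradient
steps (soft-threshold by λ, clip at zero) with backtracking line search.

Numerical choices that matter:

- **Slow co-evolution.** The M-step deliberately runs only
  `max_inner_iters = 3` proximal steps per EM iteration.  Fully re-solving
  the weighted problem each iteration makes the weights and the neighbor
  assignment leapfrog each other and the objective oscillates; with
  gradual steps the recorded objective decreases monotonically in
  practice.  The EM additionally stops at the first iteration whose
  re-estimated expectation no longer admits an improving step, returning
  the best iterate, so the reported trace is non-increasing on every run.
- **Scale equivariance.** Weights are initialized to 1/s where s is the
  grand mean absolute deviation of the features, and all convergence
  criteria are relative to the current weight scale.  Multiplying the data
  by c and λ by c then reproduces the same normalized weights and the same
  retained gene set.
- **Retention.** Weights are divided by their maximum and genes with
  normalized weight > 1e-2 are retained.  λ defaults to 0.01 (loss is the
  per-sample mean); `lambda_="auto"` runs 5-fold stratified CV scoring
  held-out 1-NN accuracy in the learned metric, preferring the sparsest λ
  on ties.
- Two grade-binning presets ship: a five-bin scheme on primary/secondary
  grades (GS≤6, 3+4, 4+3, 8, ≥9) and a four-bin scheme on the summary
  score (GS≤6, 7, 8, ≥9) for cohorts that report only the sum.
- The optimization uses one global w; per-sample weighting is not part of
  the model.

## 2. Principal tree (reversed graph embedding)

Given the selected-gene matrix X (genes × samples, centered internally),
the model learns a linear projection W (orthonormal columns, D × d),
latent sample points Y, latent anchors Z carrying a spanning tree B, and
soft assignments R by minimizing

    Σ_i ‖x_i − W y_i‖² + γ Σ_{i,j} [ r_ij ‖y_i − z_j‖² + σ r_ij log r_ij ]
      + λ Σ_{(j,j′)∈B} ‖z_j − z_j′‖² ,

with γ = 5 by default.  Alternating structure optimization solves every
block exactly, so the objective is non-increasing by construction:

- B: exact minimum spanning tree over squared anchor distances.  A
  hand-rolled Prim's algorithm is used (O(K²), first-occurrence
  tie-breaking); it is verified in the tests against a brute-force MST.
- R: row-wise soft-min, r_ij ∝ exp(−‖y_i − z_j‖²/σ) (log-sum-exp
  stabilized).  Each data point's assignments sum to one; r log r is
  continued by 0 at r = 0.
- Z: the linear system Z(γ·diag(Rᵀ1) + λL) = γYR with L the tree
  Laplacian.
- Y: (WᵀX + γZRᵀ)/(1 + γ).
- W: orthogonal Procrustes via thin SVD of XYᵀ.

Initialization is deterministic PCA (sign-fixed singular vectors); anchors
start at an even-stride subset of the projections along the first
component when K < I.  After convergence (relative objective change
< 1e-5, max 100 iterations) the tree and assignments are refreshed against
the final anchors so the stored B is the exact MST of Z.  Rank-deficient
input shrinks d with a warning.  λ and σ can be set to `"auto"`, scanned on
a log grid with the other parameter held at its grid median; the value at
the maximum-curvature elbow of the final-objective curve (normalized
second differences) is chosen, falling back to the grid midpoint when the
curve has no knee.

## 3. Progression model

The anchors and tree edges become a geometric graph with Euclidean edge
lengths.  The root is the leaf closest to the centroid of the normal
samples' latent positions; cohorts without normals use the leaf adjoining
the segment whose binary fusion covariate is closest to a 50/50 mix, which
mirrors how the disease origin behaves in practice (the earliest tumor
state contains both fusion states).  Samples project to the closest point
over all edges (clamped orthogonal projection); progression distance
(pseudotime) is the geodesic from the root to the projection, using metric
edge lengths — the tree objective penalizes squared lengths, but a
geodesic conventionally sums lengths.  Progression states are the maximal
segments between branch points; they are numbered breadth-first from the
root (ties: larger sample count, then lowest vertex id), and one
root-to-leaf path is extracted per non-root leaf, named A, B, C, … by
decreasing terminal-state occupancy.  Samples sitting exactly on a branch
point join the root-side segment.  Samples on a shared trunk belong to
every path whose edge set contains their segment.

Spanning trees over noisy anchors grow spurious twigs; segmentation
therefore supports pruning leaf segments that attract fewer than
`min_segment_samples` projections (samples re-projected after each
removal; the root segment is never pruned and at least two leaves remain).
The default is no pruning; the synthetic analyses use 10.

## 4. Trajectory statistics

**Spline basis.** All smooth fits use a natural cubic spline with df = 3:
truncated-power construction with boundary knots at the observed range and
interior knots at the 1/3 and 2/3 distance quantiles.  Linear functions
lie in its span, and the basis is linear beyond the boundaries.

**Trajectory differential expression.** Per gene and path, a Gaussian
likelihood-ratio test of a constant mean versus a spline mean, variance
profiled by ML; the statistic 2(ℓ₁ − ℓ₀) is referred to chi-square with
df = 3 (difference in mean-parameter counts — an approximation, noted).
Zero-variance genes receive statistic 0 and p = 1.  FDR is controlled by
Benjamini–Hochberg; genes at FDR ≤ 1e-4 are retained.

**Branch-dependence (BEAM-style).** For two paths, the null pools both
paths under one spline, the alternative fits path-specific intercepts and
spline coefficients.  Both designs use the basis with knots from the
pooled distances, which keeps the models nested and the LRT non-negative;
df difference is 4.  The gene universe is the union of per-path
significant genes.

**Curve clustering.** Fitted curves are min–max normalized into (−1, 1)
and clustered by PAM k-medoids under the correlation distance
d = (1 − ρ)/2 (read as parenthesized so distances lie in [0, 1]);
constant curves have undefined ρ and sit at distance 0.5 from everything,
with a warning.  BUILD + best-improvement SWAP makes the clustering
deterministic.  k = "auto" maximizes the mean silhouette over {2, …, 8}
(ties to the smaller k; all-identical curves return the minimum k with a
warning).  With k = 2 on one path, modules are labeled up/down by the sign
of the medoid's end-minus-start value.

## 5. Enrichment and driver-event statistics

- **Running-sum enrichment.** For a ±1 covariate ordered by progression
  distance (ties pre-broken by sample id, missing values dropped), a walk
  steps +1/N₊ or −1/N₋; the score is the signed maximum deviation, so a
  positive score means +1 concentrates early.  The walk closes at zero,
  asserted on every call.  Significance comes from permuting labels along
  the path (default 10,000 permutations), two-sided on |score| with the
  +1-smoothed estimator (1 + #extreme)/(1 + n_perm); a one-sided mode is
  available.
- **Spearman trend**: mid-rank Spearman ρ with the large-sample p, plus a
  df = 3 spline trend curve for display; constant covariates report ρ = 0
  with a flag.
- **Gene-set enrichment**: right-tailed hypergeometric (Fisher) test of
  module × set membership over the analysis universe, BH across sets,
  significance at FDR ≤ 1e-2; sets disjoint from the universe are skipped
  with a note.
- **Driver events**: for each binary event and each pair of successive
  states along a path, a right-tailed Fisher test of higher prevalence in
  the later state; BH pools all event × transition tests into a single
  family by default (a per-transition family is available behind a flag);
  retained at FDR < 1e-2.
- **TMB** is mutations per interrogated megabase (the denominator is an
  input); **GII** is the per-sample sum of |copy-number alteration| over
  genes.  **Binomial branch composition**: exact right-tail binomial test
  of a state's count in a branch against its cohort-wide frequency.

## 6. State transfer and fusion inference

A k-NN classifier (k = 5) under Pearson correlation distance (1 − ρ)/2
carries reference state labels to query samples over the shared gene
panel (≥ 3 genes required; restriction is logged).  Vote ties break by
the smaller mean distance among tied labels, then the lower state id;
zero-variance queries fall back to Euclidean distance with a warning.
Fusion status is inferred from a single marker gene by a two-component
Gaussian mixture (deterministic quantile-based initialization), labeling
by posterior ≥ 0.5 toward the high component; components closer than
0.1 pooled SD are declared degenerate (all −1 with a warning) and a fixed
threshold mode is available.

## 7. Synthetic cohorts and what they establish

The generator plants the structure the analyses assume, with matched
ground truth.  The fixed topology is a normal cluster at the root of a
trunk (state 1, pseudotime 0–1) that bifurcates into two limbs (states
2 and 5, 1–2), each ending in a major terminus (states 3 and 6, 2–3) with
one shorter side branch (states 4 and 7, 2–2.7).  Defaults: 40 normals,
60 tumors per state, 1,000 genes of which 100 are informative, residual
SD 1.0 and maximal trend amplitude 2.0 on the log2 scale — roughly the
signal-to-noise regime of moderately dysregulated genes in bulk RNA-seq.

Informative genes follow monotone cubic mean trends,
0.5u + 0.5(3u² − 2u³) on the relevant progression fraction u, scaled by
the effect size.  The nonzero onset slope makes branch-specific modules
diverge immediately at their branch point; a zero-slope onset would make
divergence quadratic in pseudotime and push any method's branch estimate
systematically late.  The default module layout spends 40 genes on global
up/down trends, 15 each on limb-specific trends, and 15 each on the two
side branches.  Cubic trends (not splines) keep the spline-fitting stage
honest.  Grade groups follow an ordered logit on pseudotime (cutpoints at
0.6, 1.2, 1.8, 2.4; scale `grade_noise`, default 0.5); the fusion
covariate is +1 on one limb, −1 on the other, and mixed 50/50 in the
trunk; binary events jump from a pre- to a post-transition prevalence in
the subtree past their planted transition.  `within_state_spread` < 1
concentrates samples toward segment midpoints; 0 yields seven discrete,
well-separated states and is used when a test needs unambiguous state
identity (the k-NN transfer check uses spread 0 with effect 4 and noise
0.5).  A null cohort keeps the noise model but zeroes the effect size and
flattens all event prevalences.

The companion class-labeled generator (for the selector) steps the means
of its informative features by one effect size between adjacent classes —
an ordinal analogue of grade groups.

The generator does not simulate read counts, library-size or batch
effects, or intratumor heterogeneity.  Passing the synthetic battery
shows the estimators recover the structure they model under Gaussian
log-expression noise; it does not certify performance under count noise
or confounding.

**A limit worth stating plainly:** progression states tile a continuum,
so samples near state boundaries are intrinsically ambiguous.  Under the
default conditions a Bayes-optimal classifier given the exact generative
mean curves reaches an adjusted Rand index of only ≈ 0.65 against the
planted states (the tree pipeline reaches ≈ 0.45–0.50, and its pseudotime
correlates with the truth at Spearman ρ ≥ 0.93 per path).  Hard state
labels are best read as a segmentation of a continuous process, not as
separable classes.

## 8. Problem sizes used in validation

The test suite and the acceptance script run the full battery at desk
scale: 20 cohort replicates for topology and driver recovery, 5 for
pseudotime/state agreement and gene selection, 2,000 genes for null
calibration, 10 replicates for branch-test power, exhaustive enumeration
of all ±1 sequences up to length 8 for the permutation test, and an
end-to-end CLI run (seeded) executed twice to confirm bit-identical
outputs.  The principal-tree analyses of synthetic cohorts use latent
dimension 5 (the planted structure spans about five informative
directions), λ = 400, σ = 0.1, 100 anchors and twig pruning at 10
samples; the library defaults keep the discovery settings (d = 3, γ = 5).
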
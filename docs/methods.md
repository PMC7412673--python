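# Methods

## Model

UMI counts for gene *g* in cell *c* are modeled as X_gc ~ Poisson(λ_g)
within a homogeneous cell population. Heterogeneity is modeled as a finite
Poisson mixture over K_g latent cell types with weights π_k and rates λ_kg.
The observable consequence used throughout the package is the zero
proportion: under homogeneity P(X = 0) = e^{−λ}; under a mixture it is
Σ_k π_k e^{−λ_k}, which by Jensen's inequality is at least e^{−λ̄} with
equality only when all rates coincide. Detecting "too many zeros" relative
to the gene's mean therefore detects mixing without estimating the mixture.

### Zero-inflation test

For each gene, with C cells, observed zero proportion p̂ and mean X̄
(treated as fixed — the sampling variability of e^{−X̄} is ignored):

    z = (p̂ − e^{−X̄}) / sqrt(p̂(1 − p̂) / C)

referred one-sided to N(0, 1) against the alternative p > e^{−λ}. The
denominator is the standard error of a Bernoulli proportion; a variant using
the null variance e^{−X̄}(1 − e^{−X̄})/C is available via
`gene_zero_stats(se="null")`. Degenerate genes (p̂ ∈ {0, 1}, zero standard
error) are assigned z = 0: an all-zero gene also has a zero numerator, and
zero inflation is meaningless for a gene with no zeros. Because X̄ and p̂
are negatively correlated under the null, the plug-in standard error
overstates the variance of p̂ − e^{−X̄} and the test is mildly conservative;
the measured null retention rate (fraction of |z| < 2 on homogeneous
simulations) accordingly sits above the nominal 95%.

Feature selection keeps genes with statistic strictly above the threshold
(default z > 2), ordered by descending statistic. The alternative deviance
score for one gene is

    d = 2 Σ_c [ X_c log(X_c / X̄) − (X_c − X̄) ],   0·log 0 = 0,

equal to twice the saturated-minus-fitted Poisson log-likelihood gap
(verified to 1e−10 in the tests). Its threshold is user-supplied (default
50): unlike z, d has no universal scale — it grows with C and with counts —
so high-count data sets need their own cutoff.

### Count-model diagnostics

Per-gene fits used to ask whether anything beyond a Poisson is needed:

* **Poisson**: λ̂ = X̄, closed form.
* **NB(λ, r)**, variance λ²/r + λ (r = ∞ is the Poisson): λ fixed at X̄
  (the NB MLE of the mean), r maximized on a log scale over [1e−3, 1e6] by
  bounded scalar search (tolerance 1e−8). When the sample variance does not
  exceed the mean the fit is reported at the Poisson boundary (sentinel
  r = 1e6, Poisson log-likelihood).
* **ZINB** = π₀δ₀ + (1−π₀)NB(λ, r), λ the NB-component mean: coordinate
  ascent over (π₀, log λ, log r), seeded at the NB fit with π₀ = 0, at most
  500 sweeps, converged when the log-likelihood improves by < 1e−8. Data
  with no zeros force π₀ = 0 and return the NB fit. Coordinate steps that
  would decrease the likelihood are rejected, so the nesting
  ℓ_ZINB ≥ ℓ_NB ≥ ℓ_Poisson holds by construction (asserted within 1e−6).

Nested pairs are compared by the likelihood ratio 2(ℓ_alt − ℓ_null), clamped
at 0 and referred to χ²₁. No boundary correction is applied even though r = ∞
and π₀ = 0 sit on the parameter boundary (where the asymptotic law is a
50:50 mixture of δ₀ and χ²₁); the plain χ²₁ reference is conservative and is
the convention the rest of the package is calibrated against.

Closed-form zero probabilities: Poisson e^{−λ}; NB (r/(r+λ))^r; ZINB
π₀ + (1−π₀)(r/(r+λ))^r; mixture Σπ_k e^{−λ_k}. The ZINB form carries the
(1−π₀) weight on the NB zero mass, consistent with the π₀δ₀ + (1−π₀)NB
parameterization (and with the simulator's empirical zero fractions).
`model_variance` returns the variances used in the
variance-is-a-poor-heterogeneity-indicator comparison: mixture
Σπ_k(λ_k+λ_k²) − (Σπ_kλ_k)², NB λ²/r + λ, and for ZINB the comparison-table
convention (1−π₀)²(λ²/r + λ).

### Iterative clustering

One round, starting from the cluster queued for splitting (round 1: all
cells, candidate features: all genes):

1. Zero-inflation statistics are recomputed **within the cluster's cells**
   over its candidate genes; genes with z > threshold are selected.
2. If the number selected falls below G·o (G = total genes in the input,
   constant across rounds; o = outlier proportion, default 0.01) iteration
   stops: the residual inflation is attributed to granular heterogeneity —
   e.g. inherently polymorphic immune genes — that splitting cannot resolve.
3. Selected features are transformed log(1+X), centered, and scaled to unit
   sample variance (ddof = 1; constant features stay centered, unscaled).
4. Cells are split in two by K-means (default 10 restarts, best
   within-cluster sum of squares kept) on the top PCA scores (default 10,
   capped at min(cells − 1, features)).
5. Both children inherit this round's selected genes as their candidate set
   (so candidate sets shrink along every lineage; `inherit_features=False`
   re-tests all G genes instead, for sensitivity analysis), and both are
   scored for intra-cluster variation: the log(1+X) submatrix is decomposed
   by **uncentered, unscaled** SVD and the sample variances of the first 10
   embedding components are summed. Skipping the scaling avoids inflating
   small clusters, whose embeddings would otherwise spread artificially.
6. The cluster with the highest variation is queued next (ties: lower
   cluster id). Iteration also stops at K clusters.

An alternative queueing score — mean Euclidean distance of a child's cells
from their K-means center — is available via
`split_criterion="kmeans_distance"`; the uncentered-PCA score is the default
because its no-scaling rationale is explicit.

Bookkeeping choices, fixed for reproducibility: the larger child keeps the
parent's cluster id (ties: the child containing the first parent cell); the
smaller child takes the next unused id; a master seed spawns one child seed
per round via `numpy.random.SeedSequence(master, spawn_key=(round,))`, so a
round's randomness never depends on earlier rounds' outcomes; K-means and
PCA are seeded per round. A cluster on which all cells are identical over
the selected features is marked unsplittable and the next most variable
cluster is tried; when no splittable cluster remains the run stops with
`too_few_inflated_genes`. The degenerate configuration o = 0 with zero
selected genes (where the strict test n < G·o can never fire) is routed
through the same unsplittable path.

### Differential expression

Between two clusters C₁, C₂ with group means m₁, m₂ (Poisson MLEs):

* t = (m₁ − m₂)/sqrt(m₁/|C₁| + m₂/|C₂|), two-sided standard normal. The
  variances are the Poisson plug-ins, not sample variances. Genes with both
  group means 0 get t = 0, p = 1.
* LRT: 2(ℓ(m₁) + ℓ(m₂) − ℓ(pooled)) against χ²₁, with the pooled mean
  size-weighted and the 0·log 0 convention at zero group means.

Both statistics are always reported; the caller chooses which p-value is
Bonferroni-adjusted (family size = number of genes). The exported table adds
log2((m₁+ε)/(m₂+ε)) with ε = 1/(|C₁|+|C₂|) for display only.

## Simulator

`simulate_poisson_mixture` draws X_gc ~ Poisson(λ_kg) for cell c in cluster
k, with ground-truth labels returned alongside. The default study fixture
emulates a low-UMI droplet experiment: 3 clusters × 300 cells, 2,000 genes,
5% heterogeneous genes with per-cluster rates log-uniform on [0.5, 8], the
rest sharing a rate log-uniform on [0.05, 2]. The homogeneous null fixture
is 2,000 genes × 1,000 cells with rates log-uniform on [0.05, 20], spanning
near-always-zero to never-zero genes. NB counts are produced by the
Gamma–Poisson route (cell rate ~ Gamma(r, λ/r), count ~ Poisson(rate)) so
the construction that motivates the NB model is itself exercised; ZINB adds
a structural zero with probability π₀.

What the simulator deliberately omits: per-cell library-size variation,
batch effects, ambient RNA, doublets, and gene–gene correlation. Passing
tests therefore demonstrate correctness of the statistics and the recovery
machinery under the stated models — not robustness to the full noise
structure of real droplet data, where sequencing-depth confounding in
particular can matter.

## Problem sizes and numerical choices

The test suite runs the calibration checks at 2,000 genes × 1,000 cells,
cluster recovery at 900 cells over 10 seeds, and DE null calibration at
2 × 500 cells — sizes at which the asymptotics the tests rely on are
comfortably in force while the whole suite stays fast. The DE null draws
rates log-uniform on [1, 10]: at very low rates the χ²₁ reference is
conservative by discreteness, which would measure the asymptotic regime
rather than the implementation. NB/ZINB optimizer log-likelihoods are
cross-checked against an independent grid-search-with-zoom oracle (agreement
1e−3), and the intra-cluster variation SVD against a Gram-matrix
eigendecomposition (1e−8).

## Limitations

* The gene mean in the z test is treated as fixed; no correction for the
  sampling variability of e^{−X̄}. The test is conservative as a result.
* χ²₁ reference without boundary correction for the NB/ZINB LRTs.
* PCA on the full selected-feature matrix is the computational bottleneck
  for very large cell numbers; no subsampling is implemented.
* The deviance threshold has no default that transfers across data sets.
* K-means with 2 centers assumes splits are roughly balanced in embedding
  space; elongated or nested manifolds may split along the wrong axis.
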
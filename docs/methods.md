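# Methods

## Staging model

The package stages a cross-sectional bulk RNA-seq cohort along a disease
continuum in four steps.

1. **Terminus labelling.** Donors are labelled AD (clinical diagnosis
   cogdx = 4 with Braak ≥ 4 and CERAD ≤ 2), CN (cogdx = 1, Braak ≤ 3,
   CERAD ≥ 3) or OTHER; a missing value in any rule field yields OTHER.
   Only AD/CN enter training; genes are ordered by descending log-CPM
   variance over the whole cohort, and a per-class stratified 80/20 split
   defines train/validation sets. Per-gene Z-scaling statistics are frozen
   on the training set (n−1 denominator; constant genes get sd := 1 so
   their Z-scores are 0).

2. **Sparse classifier.** A three-layer network (G → 128 sigmoid → 1
   sigmoid, hidden activations clipped into [1e−9, 1−1e−9]) minimizes
   binary cross-entropy plus a hidden-layer k-means clustering term
   (α/2 · mean ‖h − c‖², K = 2, α = 2) plus a row-wise L2,1 penalty
   (λ · Σ_g ‖W1[g,·]‖₂, λ = 0.004). The clustering term encourages the
   representation to form tight case/control clusters; the group penalty
   zeroes whole gene rows so the surviving row norms identify the genes
   the classifier actually uses.

3. **Trajectory and severity index.** The hidden representation of *all*
   donors (termini and OTHER) is reduced to 50 PCs (mean-centering only,
   deterministic sign convention: each component's largest-magnitude
   loading is positive), embedded in 3-D by UMAP (cosine metric,
   n_neighbors = 15, min_dist = 0.1, seed 2016), and clustered by k-means
   (k = 2 by default). Cluster centroids are joined by a Euclidean MST;
   the longest path starting at the origin cluster — the one with the
   highest CN fraction, falling back to the lowest mean classifier
   probability when labels are absent — seeds a polyline that is refined
   by projecting donors onto the curve, averaging coordinates within
   arc-length bins (max(20, n/25) bins), smoothing with a short moving
   average, and iterating (≤ 10 rounds or mean SI movement < 1e−3).
   SI = arc length from the origin end to each donor's nearest point on
   the curve; SI ≥ 0 and the control terminus sits at 0.

4. **Downstream analyses.** (a) OLS of each biomarker on SI plus clinical
   covariates, with pathology burdens log-transformed (offset 0 when
   strictly positive, else 1), categoricals dummy-coded against the first
   sorted level, complete-case rows only; a signed model correlation
   sign(β_SI)·√R² and a sequential (Type-I) ANOVA with SI entered first
   give the per-predictor PVE. (b) Index genes from the valley of the
   bimodal log-weight distribution, organised into unsigned co-expression
   modules (|Pearson|^β adjacency on unscaled log-CPM, β chosen by the
   scale-free criterion with default 4, TOM similarity, average-linkage
   clustering, simplified dynamic cut, eigengene merging at correlation
   ≥ 1 − 0.35). (c) Cell-type marker signatures smoothed against SI with
   a 3-df natural cubic smoothing spline, averaged per cell type,
   min-max normalized to [0, 1], optionally per sex.

External cohorts are projected without refitting: genes are reordered to
the training order (absent genes filled with the training mean, hence
Z = 0), ComBat (parametric empirical Bayes, intercept-only, via scanpy)
removes batch structure when more than one batch is present, and the
frozen scaler, network, PCA rotation, UMAP model and trajectory are
applied in sequence. Refit modes exist for the PCA and the trajectory
because either convention is defensible for a new cohort; the frozen
default keeps external SIs geometrically commensurable with the training
cohort.

### Assumptions

* The two termini genuinely bracket a continuum: intermediate donors are
  mixtures/waypoints of the same transcriptomic axis, not a different
  process.
* A single lineage suffices (one path through the MST); branching
  trajectories are out of scope.
* Expression enters log-scaled (log-CPM) and approximately Gaussian per
  gene; the classifier consumes Z-scores against the training statistics.

## Key parameters

| parameter | default | meaning / rationale |
|---|---|---|
| K, α, λ | 2, 2, 0.004 | cluster count, clustering trade-off, group-sparsity weight; the cross-validated optimum for this staging problem class, exposed in `TrainingConfig` and selectable by `cross_validate` |
| learning rate | 1e−4 | Adam base rate for the initialization phase |
| epochs (init/joint) | 1500 / 5000 | full schedule; shortened runs (e.g. 300/1000) are used throughout the test suite for speed |
| joint_lr_factor | 0.1 | the joint phase fine-tunes at a tenth of the base rate (see numerical notes) |
| batch size / hidden units | 256 / 128 | mini-batch size and hidden width |
| PCA components | 50 | trajectory input dimension |
| UMAP | 3 comps, 15 neighbours, cosine, min_dist 0.1, seed 2016 | embedding hyperparameters |
| soft power β | 4 (candidates 1–12, target scale-free R² 0.8) | unsigned adjacency exponent |
| min module size / deepSplit / merge height | 30 / 4 / 0.35 | dynamic-cut floor, sub-splitting depth, eigengene merge threshold (merge when r ≥ 0.65) |
| spline df | 3 | effective degrees of freedom of the SI smoother, matched by bisection to 0.01 df |

## Synthetic cohorts

`CohortSpec` defaults define the reference conditions used by the test
suite: 500 donors, 2000 genes, four severity-coupled modules of
300/60/40/50 genes with directions (−1, +1, +1, +1), effect size 1.5
log-CPM across the severity range, residual noise sd 1.0, terminal mass
0.4, generator seed 42.

The latent severity `s ∈ [0, 1]` is a mixture: with probability
`terminal_mass/2` each from Beta(1, 8) (healthy cluster) and Beta(8, 1)
(end-stage cluster), else Uniform(0, 1). Expression for gene g in module
m is

```
x_gi = mu_g + d_m · effect_size · f(s_i) + module_factor_sd · u_{m,i} + eps_gi
```

with baselines mu_g ~ N(4, 2²) log-CPM (typical bulk scale), a linear
link by default (a rescaled sigmoid link is available for robustness
checks), a module-private factor u_m ~ N(0, 1) and iid noise. The module
factor is essential: without it all signal genes share the single latent
`s`, within- and between-module correlations coincide, and no
co-expression method could recover the planted modules. Its default 0.5
gives within-module correlation ≈ 0.34 against ≈ 0.18 between modules of
the same direction — identifiable, while leaving the severity signal
dominant. It is also an honest cost: the factors are shared within a
module and therefore cannot be averaged away, which bounds how precisely
*any* method can read `s` back from expression (measured severity
recovery on the reference conditions is Spearman ρ ≈ 0.7–0.8, not 1.0).

Phenotypes are noisy monotone transforms of `s`: Braak
`clip(round(6s + η), 0, 6)`, CERAD `clip(round(4 − 3s + η), 1, 4)`
(lower = worse, ROSMAP convention), a 4-level diagnosis by thresholding
`s + η` at 0.30/0.55/0.75 (noise before thresholding, so labels are
unreliable near the cuts, as clinical diagnoses are), log-normal
pathology burdens `exp(c·s + η)` with c between 1.2 and 2.0, and global
cognition `−2s + 0.02(educ − 16) − 0.15·apoe4 + η`. Covariates: sex ~
Bernoulli(0.5), age at death ~ N(85, 5²), education ~ N(16, 3²),
APOE4 ~ Binomial(2, 0.1 + 0.25s), PMI ~ N(7, 2²), and comorbidity flags
with mild severity dependence. The `pheno_noise` multiplier scales all η
(0 gives noiseless phenotypes for exactness tests).

The null ("spared tissue") cohort keeps the phenotype generation but
forces the expression effect to zero — the analogue of a brain region
that the pathology largely spares. The external-cohort generator reuses
the same gene universe with per-batch additive shifts ~ N(0,
batch_shift_sd²) and mild multiplicative jitter (log-sd =
batch_shift_sd/10), with optional gene permutation/dropout to exercise
harmonization.

What the generator does **not** emulate: count-level sampling and
normalization artifacts, gene-length/GC biases, realistic co-expression
beyond the planted blocks, LD/eQTL structure, cell-type composition
shifts, and non-monotone expression programs. Passing tests therefore
demonstrate that the pipeline recovers the structures it is designed to
recover under its own generative assumptions — not that it would perform
identically on real brain data.

## Numerical choices

* **Proximal group sparsity.** The L2,1 term is handled by a proximal
  step after each Adam update (row-wise group soft-threshold with the
  Adam-preconditioned step size, averaged over the row), rather than as a
  subgradient inside Adam. A subgradient routed through the
  second-moment normalizer loses its identity: whenever other loss terms
  contribute gradient variance on a coordinate, the penalty's share of
  the normalized step shrinks toward zero and the weight distribution
  never bifurcates into used/unused genes. The proximal form applies the
  shrinkage deterministically; rows at exactly zero stay at zero until a
  data gradient revives them.
* **Joint phase as fine-tuning.** At shortened schedules the
  representation entering the joint phase is not yet saturated, and
  full-rate training with the clustering term recruits uninformative
  genes into the first layer (tightening clusters by overfitting them)
  while eroding the sparse structure built during initialization. The
  joint phase therefore runs at `learning_rate × joint_lr_factor`
  (default 0.1) with the proximal preconditioner frozen at its
  end-of-initialization value. This also slightly improves held-out
  terminus accuracy.
* **Mini-batches.** Batches are reshuffled each epoch; a trailing batch
  smaller than an eighth of the batch size is skipped (its samples return
  in the next epoch's shuffle) so near-empty batches cannot distort the
  Adam moments.
* **Weight-cut valley.** The cut separating the bimodal weight
  distribution is the deepest KDE minimum (Silverman bandwidth, 512-point
  grid on log10(weight + 1e−8)) between the two highest modes; boundary
  grid points count as modes (rows shrunk to exactly zero pile up at the
  left edge) and modes below 5% of the peak density are ignored. A
  unimodal distribution falls back to a caller-supplied threshold (or the
  median) with a prominent flag.
* **Dynamic tree cut (simplified).** All dendrogram cut heights are
  scanned for the partition with the most clusters of at least the
  minimum size; the cut is placed at the midpoint of the widest height
  interval achieving that count (high enough for modules to collect their
  weakly attached members, low enough that genes joining only near the
  root stay unassigned). Clusters of at least twice the minimum size are
  re-scanned recursively, to a depth given by deepSplit. This reproduces
  planted-block structure; it does not claim bitwise agreement with the
  reference WGCNA implementation.
* **Principal curve.** Refinement uses uniform arc-length bins rather
  than a flexible scatterplot smoother: on embeddings with dense terminal
  blobs and a sparse bridge, spline-based coordinate smoothing is
  unstable (curves loop through the blobs), while bin averaging converges
  in a few iterations. The iteration stops when the mean absolute SI
  change drops below 1e−3.
* **Smoothing spline.** The Reinsch formulation
  `(R + λ D W⁻¹ Dᵀ) γ = D ȳ`, `f = ȳ − λ W⁻¹ Dᵀ γ`, with duplicate
  abscissae collapsed under count weights. Because the second-difference
  operator D annihilates linear functions, straight lines are reproduced
  to machine precision at any λ. A single generalized eigendecomposition
  gives df(λ) = 2 + Σ 1/(1 + λθ) in closed form, so the λ matching the
  target df is found by log-scale bisection (tolerance 0.01 df).
* **Degenerate inputs.** Constant genes scale to Z = 0; genes missing at
  projection are filled at the training mean (Z = 0 contribution through
  the linear layer); an all-zero first layer yields all-zero weights with
  a warning; a constant SI (a projected cohort collapsing to one point of
  the trajectory) is reported as "no association estimable" rather than a
  spurious correlation; clusters with fewer than 3 points are merged into
  the nearest cluster before lineage inference; trajectory polylines drop
  duplicate consecutive vertices so arc length is strictly increasing.
* **Tie-breaks.** Variance sorting is stable (original order on ties);
  cross-validation ties resolve toward larger λ, then smaller K; module
  labels are ranked by size (1 = largest).

## Resolved design questions

* **Frozen vs refit projection.** For external cohorts both the PCA
  rotation and the trajectory are frozen by default (geometric
  consistency with the UMAP transform); `refit_pca`/`refit_trajectory`
  re-derive them per cohort. Neither mode is claimed to be the original
  study's exact procedure, whose wording admits both.
* **Merge threshold.** "Height 0.35" is interpreted as merging modules
  whose eigengene correlation is ≥ 1 − 0.35 = 0.65; the height is
  configurable since correlation-0.35 and height-0.35 conventions differ.
* **Missing phenotype values** propagate to OTHER at labelling and to
  complete-case dropping (with logged counts) in regression; no
  imputation.
* **Marker weights** in cell-type signatures default to uniform; per-gene
  weights are accepted but no weighting scheme is assumed.
* **Signed model R** is defined as sign(β_SI)·√R² of the full model; it
  is documented as such and not claimed to equal an SI partial
  correlation.

## Problem sizes in the test suite

Unit tests run on cohorts of 120–400 donors and 100–300 genes with a
reduced network (16–32 hidden units, 40–160 epochs). The end-to-end
checks use the reference conditions (500 × 2000, four modules) with a
shortened 300 + 1000 epoch schedule; negative-control calibration uses 50
spared-tissue cohorts of 200 donors projected through the frozen model
(10 biomarker regressions each); the λ-monotonicity check trains three
matched 150 + 300 epoch models at λ ∈ {0.004, 0.04, 0.4}. The acceptance
script repeats the reference-scale computation end to end in about a
minute on one CPU.

## Known limitations

* SI recovery on the reference synthetic conditions plateaus around
  Spearman ρ ≈ 0.7–0.8: the module-private factors bound the information
  about the latent severity, and the fixed 3-D cosine UMAP loses some of
  the remainder, particularly the fine ordering *inside* the dense
  terminal clusters where hidden activations saturate. Run-to-run seed
  variability of the recovery is a few hundredths.
* Single-lineage trajectories only; cohorts with genuinely branching
  progressions need a multi-lineage method.
* The classifier reaches perfect training accuracy on the termini at the
  default schedule; interpretation of individual gene weights should lean
  on the index-gene set and modules, not on single-gene rankings deep in
  the distribution.
* ComBat is the intercept-only parametric variant; biological covariates
  in the batch design and the nonparametric variant are out of scope.
* The dynamic tree cut is a simplification; pathological dendrograms
  (e.g. perfectly uniform merge heights) fall back to coarse partitions.
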
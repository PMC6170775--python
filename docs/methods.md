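# Methods

`taloco` implements an inference chain from talar finite-element (FE)
stress fields and 3-D landmark configurations to locomotor-category
inference, for a comparative sample of platyrrhine (New World monkey)
tali: 40 extant species in three locomotor classes (arboreal
quadruped, leaper, clamber/suspensory) and 10 Miocene fossils of
unknown class. This note documents the models, the defaults and why,
the numerical choices, and what the synthetic data do and do not show.

## Mesh-weighted stress statistics

An adaptive FE mesh concentrates small elements where geometry is
fine, so plain per-element summaries over-weight densely meshed
regions. For element von Mises stresses σ_i (MPa) and volumes v_i
(mm³) we compute the mesh-weighted arithmetic mean
MWAM = Σσ_i v_i / Σv_i and volume-weighted percentiles M25–M95, with
the mesh-weighted median MWM = M50. The percentile uses the
left-continuous step (inverse-CDF) definition — the smallest σ at
which the volume-weighted cumulative distribution reaches the target
fraction; ties pool their volume at one step. This definition is
deterministic and exactly checkable against a brute-force oracle that
expands elements into volume-proportional copies; a piecewise-linear
interpolated variant is available behind a flag. Percentiles are
volume-weighted by default (plain variants derive from unit volumes).

Quasi-ideal-mesh (QIM) screening compares the unweighted mean/median
with their weighted counterparts: PEofAM = |AM − MWAM|/MWAM·100,
PEofM likewise. A mesh is quasi-ideal when both errors are at or
below a threshold, default 2% (configurable; the literature the
procedure follows does not print a universal cut-off). The plain
median uses the lower-median convention for even element counts, so
PEofM is reproducible without interpolation ambiguity.

The applied load metadata follows a basic quadrupedal stance: "body
weight force" = 0.30 · (mass in kg) · 9.81 m s⁻², applied at the
trochlea with the sub-talar surface constrained. The FE solve itself
(linear elastic cortical bone, E = 20.7 GPa, ν = 0.3) is out of scope;
these constants are carried as run metadata only.

## Intervals' method

A stress field becomes a fixed-length feature vector: the percentages
of total model volume in N equal-width stress bins on [0, FT_upper).
Defaults: N = 10; FT_upper = the ceiling of the maximum M95 across
specimens, so the top of the scale is set by the sample rather than
guessed. Elements at or above FT_upper are accumulated into the top
bin, preserving the sum-to-100 invariant (a discard variant exists
behind a flag and is flagged in output). Bin edges nest, so profiles
at N = 2k collapse exactly onto profiles at N = k — a property test.

The convergence ladder (candidates 5, 10, 15, 25, 50) picks the
smallest N whose between-specimen Euclidean distance matrix correlates
above 1 − tol (default tol = 0.01, Pearson on upper triangles) with
the next candidate's; identical profiles count as converged, and a
never-converging ladder returns the largest candidate with a warning.

Pre-processing for classification: per column, zeros are offset by
half the smallest positive value (interval percentages can be exactly
0 and Box-Cox needs positive input), Box-Cox λ is estimated by maximum
likelihood (scipy), then the column is centred and scaled to unit
standard deviation. λ, offset, mean and sd are stored and re-applied
verbatim to fossil rows — fossils never influence the transform.
Constant columns skip Box-Cox and are centred only, with a warning.

## Geometric morphometrics

Generalized Procrustes analysis: configurations are centred, scaled to
unit centroid size, and iteratively rotated to the current mean
(rotations only, no reflections; SVD with determinant correction)
until the mean shape moves < 1e-10 or 100 iterations. The final
orientation is standardized to the principal axes of the mean shape
with a deterministic sign convention, so the output is invariant (to
1e-8) under similarity transforms of any input. The 30 landmarks are
treated as fixed (no sliding semilandmarks).

Shape PCA uses the covariance matrix of the vectorised Procrustes
coordinates (SVD of the centred data); scores reconstruct the data to
1e-8. Broken-stick retention keeps the longest initial run of
components whose observed variance proportion strictly exceeds
b_k = (1/p)Σ_{i=k..p} 1/i, with p the count of eigenvalues above
1e-12 of the largest; a strict comparison is made robust to float
rounding with a 1e-12 relative tolerance, and a single positive
component is always retained.

Fossil handling: GPA is run jointly over extant + fossil specimens
(one shape space), but the PCA is fitted on extant specimens only and
fossils are projected afterwards, so fossils influence neither the
ordination nor any model fit. Both behaviours are explicit in the
pipeline code.

## Phylogenetic comparative statistics

All methods condition on a rooted, branch-length phylogeny through the
Brownian-motion covariance C, with C[i,j] the root-to-MRCA path
length. Polytomies are accepted as-is; zero-length terminal branches
are raised to 1e-8 × tree depth with a warning. The inverse square
root of C is computed by symmetric eigendecomposition (tolerance 1e-10
on eigenvalues), not Cholesky, so the whitening transform is
rotation-consistent.

* **Kmult** (multivariate phylogenetic signal): with â the GLS root
  estimate, K is the ratio of the raw to the C-whitened residual sum
  of squares, divided by its Brownian expectation
  (tr C − n/Σ(C⁻¹))/(n−1); K ≈ 1 under Brownian motion (verified by
  simulation: mean over 500 replicates on a 40-tip tree within
  [0.9, 1.1]). Significance by shuffling rows across tips.
* **PGLS**: both sides are premultiplied by C^{−1/2}; the statistic is
  the Procrustes-style SS_model/SS_residual F ratio summed over trait
  columns. Significance uses residual randomization (permuting
  reduced-model residuals in the whitened space) by default — it is
  exactly calibrated in our null simulations — with tip shuffling
  behind a flag, since the choice of scheme is genuinely open.
* **Two-block PLS**: SVD of the cross-covariance of column-centred
  blocks; r-PLS is the correlation of the first score pair; the
  permutation statistic is the first singular value, permuting rows of
  the second block. The phylogenetic variant GLS-centres both blocks
  on â and whitens by C^{−1/2} first; on a star tree it reduces
  exactly to the standard PLS (tested to 1e-8).
* **Phylomorphospace**: internal nodes are placed at maximum-likelihood
  Brownian ancestral states, obtained by solving the weighted-Laplacian
  normal equations (weights 1/branch-length) per ordination axis.

Permutation conventions everywhere: the observed statistic counts in
the null set, so p ≥ 1/(n_perm + 1); the default is 9999 permutations
in the analysis drivers, and all permutation streams are seeded and
recorded. The pipeline defaults to 999 to keep full end-to-end runs
to a few minutes; statistics are unaffected, only the granularity of
p-values.

## Group-difference testing

PERMANOVA on Euclidean distances over the stress percentiles:
SS_total = (1/n)Σ_{i<j}d²_ij, the within analogue per group, pseudo-F
= [SS_among/(g−1)]/[SS_within/(n−g)], p by unrestricted label
shuffles. No internal standardization — features are standardized
upstream, explicitly, where wanted. Pairwise contrasts run PERMANOVA
per group pair with Holm step-down correction across pairs. The
normality screen is Mardia's multivariate skewness and kurtosis tests
(the screen's outcome — rejection for right-skewed stress data — is
what motivates the non-parametric test).

## Classifier bench

Six families, spanning the main model classes: LDA; a
cost-complexity-pruned decision tree (CART); k-nearest neighbours
(k ∈ {3,5,7,9}); Gaussian naive Bayes; soft-margin linear SVM
(one-vs-one, cost ladder 0.25–16); random forest (bench grid 200
trees, mtry ∈ {2,3}; a dedicated tuner sweeps trees ∈ {100..2000} ×
mtry ∈ {2..6}). Evaluation is leave-group-out cross-validation: 200
random stratified 75/25 splits, scoring overall accuracy and Cohen's
Kappa per repeat; 95% intervals are percentile intervals across
repeats. Splits are stratified because the classes are imbalanced
(19/14/7); no rebalancing or class weights are applied. Grid winners
maximize mean accuracy, ties broken toward the simpler model (smaller
cost; fewer trees, then smaller mtry).

Fossil posteriors come from the best family per route refitted on all
extant rows: native probabilities for LDA/NB/KNN, vote fractions for
trees/forests, and Platt-style sigmoid calibration fitted by internal
5-fold CV for the SVM (the probability mechanism is not dictated by
the method, so the choice is documented here). Calibrated SVM
posteriors saturate below ~0.85 even on cleanly separable data — an
inherent property of sigmoid calibration at small n, visible in the
tests.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis
assumes, at the study's scale: a pure-birth ultrametric tree (depth 1)
over 40 species; terminal branches extended by the waiting time to the
next uncounted speciation event so no branch is zero; locomotor groups
assigned to clades (19/14/7), which puts phylogenetic signal into the
labels; shapes evolving by Brownian motion (rate 5e-4 per coordinate)
around group-specific mean shapes (offset norm 0.1, mutually
orthogonal directions) plus i.i.d. landmark noise (sd 0.005), wrapped
in a random similarity transform that GPA must remove; lognormal
element volumes and lognormal stresses with group medians 12/8/5 MPa
(clamber/suspensory > arboreal quadruped > leaper) and element-level
spread 0.6 on the log scale. Species within a group additionally vary
in overall stress scale (log-sd 0.3) and talar volume (log-sd 0.5):
without species-level variance, every species in a group would share
one stress distribution and percentile features would separate groups
perfectly, which no comparative dataset does. The 0.3 value was set
by a variance decomposition on the log scale to put the PERMANOVA R²
in the regime the method is designed for (≈0.5 between-group share).

Fossils are drawn from known groups near the group mean shape and
delivered unlabeled; the truth is stored only in the bundle manifest
for recovery scoring. A `zero_effect()` variant removes group shape
offsets, equalizes stress medians, and randomizes the group-to-tip
assignment — the last because with groups on clades, Brownian motion
alone makes clades (hence labels) separable, and "no effect" must mean
the labels carry no signal at all. All randomness flows from one
master seed through named substreams.

What passing on synthetic data does **not** show: the fields are not
biomechanically realistic (no mesh geometry, no stress gradients along
the bone, element stresses are exchangeable within a specimen); the
landmark template is a sphere-octant grid, not a talus; group shape
differences are isotropic displacements rather than the anatomically
structured trochlear differences of real tali. The synthetic results
validate the statistical machinery and its calibration, not any
biological claim.

## Problem sizes and runtime

Defaults used by the test suite and the acceptance script: 40 extant +
10 fossil specimens, 2,000 elements per field, 200 CV repeats, 999
permutations in the end-to-end runs (9999 in the analysis drivers);
type-I-error simulations use 1,000 nulls at 199 permutations, and the
Brownian Kmult calibration uses 500 replicates on a 40-tip tree.
These sizes give a full pipeline run in roughly three minutes on one
CPU.

## Known limitations

* PGLS assumes Brownian residual covariance only; no OU/EB models.
* The Intervals' convergence rule and FT_upper rule are package
  choices (the originating procedure is not fully printed anywhere);
  both are config-exposed and logged.
* Mardia's test substitutes for an unnamed normality screen.
* With n = 40 and imbalanced classes, leave-group-out accuracy has
  wide resampling intervals; winners of the bench are reported with
  those intervals, and single-point accuracies should not be
  over-read.
* Joint GPA with fossils included slightly perturbs extant Procrustes
  coordinates relative to an extant-only superimposition; both modes
  are available, the joint mode is the default.
* No feature scaling is applied inside the bench (Procrustes PC scores
  are used raw, as is standard after superimposition), so
  scale-sensitive families — the linear SVM in particular — can
  underperform on the small-magnitude shape scores while
  scale-invariant families (LDA, trees) are unaffected; the bench
  reports this honestly rather than silently rescaling.
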
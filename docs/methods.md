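# Methods

This note documents the models, estimators, defaults and numerical choices
behind perturbkit, and what the synthetic-data tests do and do not show
about real data.

## Data model

A `PerturbationDataset` is a cells × features matrix (dense or sparse; raw
counts or normalized expression) with a per-cell annotation table
(`perturbation` label required, optional split/batch label, anything else),
named low-dimensional representations (cells × d) and named layers
(cells × features). Controls are designated per call by a control label
rather than stored, so one dataset can be analysed against different
references. Group order is lexicographic everywhere, which makes pairwise
matrices and CSV outputs reproducible byte for byte. Dense and sparse
inputs are required to agree within 1e-8; group variances use the unbiased
n−1 denominator and are defined as 0 for singleton groups, with an ε guard
(default 1e-8) wherever a variance is divided by.

## Guide-assignment mixture

Per guide, zero-count cells are negative outright. Non-zero counts are
log2-transformed and fit by EM with two components: a background component
and a Gaussian signal component in log2 space. The default background is a
Poisson on the raw counts (its likelihood evaluated at the observed
integers) with rate initialised from the low mode; `method="gaussian"`
instead fits two Gaussians in log2 space. At realistic separation
(background around a few counts, signal around 2⁶) the two parameterisations
classify identically; the pure-Gaussian variant is the one with the exact
invariance that doubling all counts shifts both component means by +1 and
leaves classifications unchanged. EM uses a deterministic
k-means-style split of the log2 values for initialisation, a relative
log-likelihood tolerance of 1e-6, at most 500 iterations, and sd floors of
0.05 to prevent component collapse. A cell is positive when its posterior
for the higher-mean component strictly exceeds 0.5 (exactly 0.5 is
negative — conservative). Guides with fewer than 10 non-zero cells or fewer
than 2 distinct non-zero values are skipped with a warning, never aborting
the matrix. Cells positive for more than `max_assignments` (default 5)
guides are labelled `multiple` and receive no assignments; their per-guide
positivity remains inspectable. The mixture is fit per guide over all
cells; fitting per lane would be a reasonable alternative where ambient
contamination differs strongly between lanes.

## Perturbation signature and KO/NP classification

The signature subtracts a control reference from each cell's expression:
in `nn` mode the mean expression of the k = 20 nearest control cells,
found by exact brute-force Euclidean search in a chosen representation
(exact search is used throughout; an approximate index would only matter
beyond ~50k cells); in `split_by` mode the mean of all control cells in
the cell's split. Signatures are linear in the expression, so a global
per-gene shift cancels.

Classification runs per target group, iterating at most `max_iter` = 10
times:

1. **Feature selection.** Candidate features must pass a per-gene Welch
   t-test between the current KO set's signatures and the control
   signatures at Benjamini–Hochberg-adjusted α = 0.05; the
   `n_top_features` = 100 candidates with the largest |t| are kept. The
   significance gate matters: selecting by magnitude alone manufactures
   separation out of noise under a null perturbation (a selection bias),
   which would misclassify null targets as KO. No significant feature →
   the target does not separate → all cells NP, with a warning.
2. **Scoring.** Each cell's signature, restricted to the selected
   features, is projected onto the unit vector from the control-mean
   signature to the KO-set-mean signature.
3. **Mixture.** A two-Gaussian model is fit to the targeted cells' scores
   by EM with the null component's mean and sd *fixed* at the control
   cells' score statistics and the KO component and mixture weight free
   (weight initialised at 0.5; anchoring the null on controls prevents the
   degenerate all-KO fixed point). The two-component fit must beat a
   single control-shaped Gaussian by BIC (3 free parameters) and place the
   KO mean above the null mean; otherwise the target is declared
   non-separating and all cells NP.
4. **Assignment.** Cells with posterior P(KO) > threshold (default 0.5;
   exactly at threshold → NP) are KO; iteration stops when assignments
   stabilise.

Control cells are always classed `control` with NaN posterior. CRISPRi and
CRISPRa inputs are accepted; a log message notes that the escape model is
only meaningful for those modalities when perturbed and unperturbed-like
states separate cleanly. The LDA projection is fit on KO + control cells
with their perturbation labels (NP escapees would blur class structure) and
projects all cells; `n_components` is capped at #classes − 1.

## Distance catalog

Mean-based metrics (mse, euclidean, mae, cosine, pearson, r2, t_stat,
kendall, spearman, sym_kl) consume per-group summaries only; distribution
metrics (mmd, edistance, ks, wasserstein, nb_ll, classifier metrics)
consume full matrices. Specific choices:

- **MMD / energy distance.** Default estimators are V-statistics: the
  within-group sums include the diagonal and are normalised by N². These
  are exactly zero on identical groups, and linear-kernel MMD² then equals
  ‖x̄ − ȳ‖² identically. The U-statistic (unbiased, N(N−1)) forms are
  available via `unbiased=True`; they have smaller bias but negative
  self-distance of order −1/N.
- **t_stat.** Per-gene Welch-style terms (x̄ᵢ − ȳᵢ)/√(s²ₓᵢ/nₓ + s²ᵧᵢ/nᵧ + ε),
  averaged as absolute values by default so the metric is symmetric;
  `signed=True` averages the signed terms (antisymmetric, sign carries the
  net direction of change).
- **ks.** Exact two-sample KS statistic per gene (ECDF sup-distance),
  averaged over genes.
- **sym_kl.** Per-gene Gaussian KL in both directions, averaged:
  ½[KL(X‖Y) + KL(Y‖X)], variances floored at ε. A discrete variant for
  probability vectors is provided (`sym_kl_discrete`).
- **kendall / spearman.** The rank-statistic forms
  (1 − τ_b)·n(n−1)/4 and 6Σd²ᵢ/(n(n²−1)) on average ranks; with ties the
  Spearman form is the plain rank-difference statistic rather than
  1 − ρ exactly.
- **wasserstein.** First-order optimal transport with Euclidean ground
  cost and uniform weights, solved exactly (linear assignment for equal
  group sizes, transportation LP via HiGHS otherwise) up to 2,000
  cells/group, and by log-domain Sinkhorn (reg 0.05 on the normalised cost)
  above, with a warning.
- **nb_ll.** Per-gene NB(μ, θ) fit on X by method of moments
  (θ = μ²/(var−μ)), restricted to overdispersed genes (var > mean) since
  the NB requires overdispersion; the distance is the *negative* mean
  log-likelihood of Y under those fits, so closer groups score lower. The
  diagonal of a pairwise matrix is not zero by definition, and the metric
  is asymmetric.
- **Classifier metrics.** "Linear classifier + softmax" is multinomial
  logistic regression (scikit-learn, lbfgs, max_iter 1000).
  `classifier_cp` trains control-vs-perturbed with a seeded 20% holdout of
  the perturbed group and returns the mean held-out control-class
  probability (≈0.5 for indistinguishable groups, →0 for separable ones).
  `classifier_proj` trains on all cells *outside* P_i plus all controls and
  returns the mean control-class probability over P_i — a measure of how
  control-like P_i looks relative to the other perturbations, requiring at
  least one other perturbation to train against.

Asymmetric metrics: r2, classifier_cp, classifier_proj, nb_ll; all others
are symmetric and the pairwise driver computes each unordered pair once.
Per-pair failures in a pairwise matrix become NaN with a warning rather
than aborting the run.

**Permutation test.** Observed distance vs. `n_perm` label reshuffles of
the pooled two groups (sizes preserved), seeded;
p = (1 + #{null ≥ observed})/(1 + n_perm) — the add-one estimator is never
0 and counts ties toward the null, making the test conservative and valid.
`n_perm ≥ 19` is enforced since p cannot reach 0.05 below that.

## Model-evaluation metrics

`de_ranking_correlation` ranks genes by per-gene Welch t statistics for
control-vs-real and control-vs-predicted and returns the Spearman
correlation of the rankings; genes with undefined t (constant in both
groups) rank as 0 with a warning. Note that both rankings share the control
matrix, so shared control sampling noise puts a positive floor under the
null correlation of roughly var(x̄)/(var(x̄) + var(ȳ)); with many more
control than perturbed cells (as in real screens) the floor is small.
`mean_variance_density_distance` compares the per-gene (mean, variance)
clouds of real and predicted matrices via 2-d Gaussian KDEs (Scott's rule)
on a shared 100 × 100 grid spanning the union of ranges (5% padding); the
shared grid makes it symmetric, and identical inputs give exactly 0. Its
magnitude scales inversely with the covered area, so it is comparable only
across predictions for the same dataset.

## Perturbation spaces and label transfer

Pseudobulk aggregates member cells columnwise (mean default; mean
pseudobulk commutes with cell duplication). Centroid returns the actual
member cell closest to the group mean (ties → lowest cell index), so rows
are always real cells. The MLP space trains a one-hidden-layer network
(512 units default, batch normalization, ReLU, softmax) with Adam
(lr 1e-3) and cross-entropy on class-balanced batches — every class
resampled with replacement to the majority size each epoch — for at most
40 epochs with early stopping on a 10% validation split (patience 3). It
is implemented directly in numpy; batch-norm inference statistics use an
adaptive-momentum running average so they are calibrated even after few
updates, and the per-cell embedding is the penultimate-layer activation.
Per-perturbation rows are means of member-cell embeddings (any other
aggregation can be applied to `cell_embedding` downstream). The logreg
space fits a seedless deterministic one-vs-rest logistic regression per
perturbation (max_iter 1000) and uses the coefficient vector as the
embedding. Cluster spaces wrap scikit-learn k-means (seeded) and DBSCAN
and report ARI and NMI against the perturbation labels as the
concretisation of cluster/perturbation overlap.

Label transfer finds each unlabeled cell's k nearest labeled cells
(Euclidean, exact) and votes with Gaussian-kernel connectivity weights
exp(−d²/2bw²), bandwidth = that cell's mean neighbor distance (all-equal
distances degrade gracefully to uniform weights). Uncertainty is the
Shannon entropy (base 2, bits — so a balanced two-way tie is exactly 1) of
the normalised weighted label distribution; argmax ties break
lexicographically.

## Synthetic data

Control cells draw per-gene NB(μ_g, θ) counts, with μ_g lognormal around a
base mean (default 5, σ = 0.25 in log space) for gene-level heterogeneity
and θ = 2 (variance μ + μ²/θ). Each perturbation multiplies its affected
genes' means by exp(effect): effect sizes are natural-log fold changes.
Escapees are full draws from the control model that keep the targeted
label — the strongest null, matching the NP concept. Optional per-cell
library-size factors are lognormal with a given CV (default 10%) applied by
Poisson thinning/amplification; a log1p median-depth-normalized layer is
emitted alongside raw counts, and a two-lane split column makes
split-referenced signatures testable. Guide simulation plants one true
guide per cell (low MOI) or Poisson-many (high MOI) with counts
2^Normal(6, 0.5) over Poisson(0.3) ambient background.

The prediction-pair generator draws per-gene log-fold effects from
Normal(0, 1) across *all* genes — a spectrum of up- and down-regulation,
which is what makes a differential-expression *ranking* informative — and
scales them by the prediction quality; its control group is 10× the
perturbed group (2,000 vs 200 cells) both for realism and to keep the
shared-control correlation floor described above small.

All generators are pure functions of parameters and seed. They do **not**
emulate gene–gene correlation, batch effects, zero-inflation beyond NB, or
cell-state heterogeneity within a condition; passing tests therefore
demonstrate correctness of the estimators and classifiers under the stated
generative model, not robustness to the full messiness of real screens.

## Problem sizes and defaults used in the automated checks

Metric axioms run on 200 random group pairs of 5–15 cells × 3–8 features;
oracle equivalence on ≤ 20 × 10 instances against double-loop references;
permutation calibration on 400 null datasets (30 + 30 cells, 50 genes) at
n_perm = 199, expecting a rejection rate in [0.03, 0.08] at α = 0.05;
guide recovery on 1,000 cells × 20 guides; escapee recovery on 200 + 200
cells × 500 genes across 3 seeds. These sizes keep the whole suite and the
acceptance script in the tens of seconds on one CPU while leaving the
statistical assertions well-powered.

## Known limitations

- The Mixscape-style classifier assumes a single dominant response
  direction per target; heterogeneous or multimodal responses would need
  more components.
- The BIC/BH gates make the all-NP call conservative: very weak but real
  perturbations may be declared non-separating.
- `nb_ll` requires raw counts and at least one overdispersed gene.
- The Sinkhorn path of the Wasserstein distance is an approximation; its
  regularisation (0.05 of the max cost) trades accuracy for speed above
  2,000 cells per group.
- The hand-rolled MLP targets small-to-medium inputs on CPU; there is no
  GPU path.
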
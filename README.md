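# perturbkit

Analysis toolkit for single-cell perturbation screens: guide-RNA
assignment, detection of cells that escaped CRISPR perturbation,
statistical distances between perturbation conditions with Monte-Carlo
permutation tests, perturbation-level embeddings, and metrics for
evaluating perturbation-response prediction models — all testable end to
end on built-in synthetic data with known ground truth.

## Who this is for

Computational biologists analysing Perturb-seq / CROP-seq-style screens or
drug-treatment scRNA-seq, who need to (1) link cells to the guide or
treatment they received, (2) separate truly perturbed cells (KO) from
escapees (NP), (3) quantify *how different* two perturbation conditions
are, with a p-value, and (4) compress thousands of cells per perturbation
into one interpretable embedding point.

## What it computes

**Guide assignment.** For each guide, cells with non-zero counts are
log2-transformed and modelled as a two-population mixture (low ambient
background vs. high true-signal component, fit by EM); a cell is positive
for a guide when its posterior responsibility for the high component
exceeds 0.5. Cells positive for 1–5 guides are `assigned`, for more
`multiple`, for none `negative`. A simple argmax-over-threshold assigner is
also provided.

**Perturbation signatures and KO/NP classification.** A cell's signature
is its expression minus a control reference — the mean of its *k* = 20
nearest control cells in a low-dimensional representation, or the mean of
all control cells in the same lane/batch. Targeted cells are scored by
projecting their signatures onto the KO-vs-control direction (restricted
to significantly differential features) and classified with a two-Gaussian
mixture whose null component is anchored on the control cells: posterior
P(KO) > 0.5 → KO, otherwise NP. A linear-discriminant projection
visualises the result.

**Distances.** Seventeen metrics between cell groups X (perturbed) and Y
(control), including

- MSE `1/n Σ (x̄ᵢ − ȳᵢ)²`, MAE, Euclidean distance between group means,
- energy distance `E(X,Y) = 2δ_XY − δ_X − δ_Y` on mean pairwise Euclidean
  distances,
- linear-kernel MMD² (equal to `‖x̄ − ȳ‖²` for the default estimator),
- per-gene two-sample Kolmogorov–Smirnov statistic averaged over genes,
- first-order Wasserstein (earth mover's) distance via exact optimal
  transport (entropic approximation above 2,000 cells/group),
- symmetrised Gaussian Kullback–Leibler divergence, per-gene t statistic,
  cosine / Pearson / Spearman / Kendall distances on mean vectors, an
  asymmetric R² distance, negative-binomial log-likelihood of Y under
  per-gene fits on X, and two classifier-probability metrics.

Any metric can drive a Monte-Carlo permutation test: group labels are
reshuffled `n_perm` times and `p = (1 + #{null ≥ observed}) / (1 + n_perm)`.

**Perturbation spaces.** Pseudobulk (mean/sum/median), centroid (the real
cell closest to the group mean), the penultimate layer of an MLP trained to
predict the perturbation, and one-vs-rest logistic-regression coefficient
vectors; plus k-means/DBSCAN cluster spaces scored against perturbation
labels (ARI, NMI) and k-NN label transfer with Shannon-entropy uncertainty.

**Model evaluation.** Spearman correlation of differential-expression
rankings (control vs. real and control vs. predicted), and a kernel-density
distance between the per-gene mean–variance landscapes of real and
predicted data.

## Worked example

```bash
python examples/mixscape_workflow.py
```

```
pert1: called NP 19.0% (simulated escapees 19.0%), per-cell agreement with truth 100.0%
pert2: called NP 23.0% (simulated escapees 23.0%), per-cell agreement with truth 100.0%

LDA embedding: 600 cells x 2 discriminant axes (fit on KO + control cells, NP cells projected)
```

The simulation plants 20% escapees among the targeted cells (escapees are
drawn from the control expression model but keep their target label); the
classifier recovers the per-seed realised escape fractions exactly and
labels every cell correctly. The other scripts in `examples/` demonstrate
the distance catalog and permutation test, guide assignment, perturbation
spaces, and label transfer / model evaluation, each printing the numbers it
computes and what they mean.

From Python:

```python
from perturbkit import simulate_expression, pairwise_distances, distance_test

ds, truth = simulate_expression(n_groups=3, cells_per_group=100, seed=0)
d = pairwise_distances(ds, metric="edistance", representation="lognorm")
print(d.to_frame().round(3))
test = distance_test(ds, "pert1", "control", metric="edistance",
                     representation="lognorm", n_perm=999, seed=0)
print(test.p_value)   # 0.001 — the smallest attainable at n_perm = 999
```

A thin CLI mirrors the library (`perturbkit simulate`, `assign-guides`,
`signature`, `mixscape`, `distance`, `distance-test`, `space`,
`label-transfer`, `evaluate`); every run writes a JSON manifest with its
parameters and seed so it can be reproduced exactly.

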
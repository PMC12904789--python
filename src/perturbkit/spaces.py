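"""Perturbation-level embeddings, cluster spaces, and label transfer.

A perturbation space collapses the per-cell view into one point per
perturbation:

* pseudobulk — columnwise mean/sum/median of each group's cells;
* centroid — the *actual member cell* closest to the group mean in a
  chosen representation;
* mlp — mean of member cells' penultimate-layer activations of a
  feed-forward classifier trained to predict the perturbation;
* logreg — the coefficient vector of a one-vs-rest logistic regression per
  perturbation.

Cluster spaces instead cluster cells (k-means or DBSCAN) and score how well
the clustering recovers the perturbation labels (adjusted Rand index and
normalized mutual information). Label transfer propagates annotations to
unlabeled cells by connectivity-weighted k-nearest-neighbor voting, with a
Shannon-entropy (bits) uncertainty per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN, KMeans
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.neighbors import NearestNeighbors

from ._mlp import MLPClassifier
from .core import PerturbationDataset, as_dense, select_representation, split_groups

__all__ = [
    "PerturbationSpace",
    "ClusterSpaceResult",
    "LabelTransferResult",
    "pseudobulk_space",
    "centroid_space",
    "mlp_space",
    "logreg_space",
    "cluster_space",
    "label_transfer",
]


@dataclass
class PerturbationSpace:
    """One embedding row per perturbation."""

    perturbation_labels: list
    embedding: np.ndarray
    provenance: str  # "pseudobulk" | "centroid" | "mlp" | "logreg"
    cell_embedding: np.ndarray | None = None  # mlp only

    def __post_init__(self):
        if self.embedding.shape[0] != len(self.perturbation_labels):
            raise ValueError("one embedding row required per perturbation")
        if not np.isfinite(self.embedding).all():
            raise ValueError("perturbation embedding contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.embedding, index=self.perturbation_labels)


@dataclass
class ClusterSpaceResult:
    cluster_ids: np.ndarray  # -1 allowed for DBSCAN noise
    method: str
    params: dict
    ari: float
    nmi: float


@dataclass
class LabelTransferResult:
    predicted: np.ndarray
    uncertainty: np.ndarray  # Shannon entropy, bits

    def to_frame(self, cell_ids=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {"predicted": self.predicted, "uncertainty": self.uncertainty}
        )
        if cell_ids is not None:
            df.insert(0, "cell_id", cell_ids)
        return df


def pseudobulk_space(
    ds: PerturbationDataset,
    groupby: str = "perturbation",
    mode: str = "mean",
    representation: str = "X",
) -> PerturbationSpace:
    """Columnwise aggregate (mean/sum/median) of each group's cells."""
    if mode not in ("mean", "sum", "median"):
        raise ValueError(f"unknown mode '{mode}'")
    groups = split_groups(ds, groupby)
    rep = as_dense(select_representation(ds, representation))
    agg = {"mean": np.mean, "sum": np.sum, "median": np.median}[mode]
    rows = [agg(rep[idx], axis=0) for idx in groups.values()]
    return PerturbationSpace(
        perturbation_labels=list(groups),
        embedding=np.vstack(rows),
        provenance="pseudobulk",
    )


def centroid_space(
    ds: PerturbationDataset,
    groupby: str = "perturbation",
    representation: str = "X",
) -> PerturbationSpace:
    """The member cell closest to each group's mean point.

    The returned rows are always actual cells' coordinates; equidistant
    ties go to the lowest cell index.
    """
    groups = split_groups(ds, groupby)
    rep = as_dense(select_representation(ds, representation))
    rows = []
    for idx in groups.values():
        centroid = rep[idx].mean(axis=0)
        d2 = ((rep[idx] - centroid) ** 2).sum(axis=1)
        rows.append(rep[idx[int(np.argmin(d2))]])  # argmin: first == lowest index
    return PerturbationSpace(
        perturbation_labels=list(groups),
        embedding=np.vstack(rows),
        provenance="centroid",
    )


def mlp_space(
    ds: PerturbationDataset,
    groupby: str = "perturbation",
    representation: str = "X",
    hidden_units: int = 512,
    batch_size: int = 256,
    max_epochs: int = 40,
    learning_rate: float = 1e-3,
    val_fraction: float = 0.1,
    patience: int = 3,
    seed: int = 0,
) -> PerturbationSpace:
    """Perturbation space from a feed-forward classifier's hidden layer.

    A one-hidden-layer network (batch normalization + ReLU, softmax output)
    is trained with cross-entropy on class-balanced oversampled batches to
    predict each cell's perturbation, stopping early when the held-out
    validation loss stops improving or at ``max_epochs``. The per-cell
    embedding is the penultimate-layer activation (width =
    ``hidden_units``); per-perturbation rows are the means of member-cell
    embeddings.
    """
    groups = split_groups(ds, groupby)
    if len(groups) < 2:
        raise ValueError("mlp_space needs at least 2 perturbation labels")
    if any(len(idx) < 2 for idx in groups.values()):
        raise ValueError("every perturbation needs at least 2 cells")
    rep = as_dense(select_representation(ds, representation))
    labels = ds.obs[groupby].to_numpy(dtype=object).astype(str)
    clf = MLPClassifier(
        hidden_units=hidden_units,
        batch_size=batch_size,
        max_epochs=max_epochs,
        learning_rate=learning_rate,
        val_fraction=val_fraction,
        patience=patience,
        seed=seed,
    ).fit(rep, labels)
    cell_emb = clf.hidden_activations(rep)
    rows = [cell_emb[idx].mean(axis=0) for idx in groups.values()]
    space = PerturbationSpace(
        perturbation_labels=list(groups),
        embedding=np.vstack(rows),
        provenance="mlp",
        cell_embedding=cell_emb,
    )
    space.classifier_ = clf
    return space


def logreg_space(
    ds: PerturbationDataset,
    groupby: str = "perturbation",
    representation: str = "X",
    max_iter: int = 1000,
) -> PerturbationSpace:
    """One-vs-rest logistic-regression coefficients per perturbation.

    Each perturbation's embedding row is the coefficient vector of a binary
    logistic regression separating its cells from all others, fit on the
    chosen representation (d = representation width).
    """
    groups = split_groups(ds, groupby)
    rep = as_dense(select_representation(ds, representation))
    n = rep.shape[0]
    rows = []
    for label, idx in groups.items():
        if len(idx) < 2 or n - len(idx) < 2:
            raise ValueError(
                f"perturbation '{label}' needs >= 2 member and >= 2 "
                "non-member cells"
            )
        y = np.zeros(n, dtype=int)
        y[idx] = 1
        clf = LogisticRegression(max_iter=max_iter)
        clf.fit(rep, y)
        rows.append(clf.coef_.ravel())
    return PerturbationSpace(
        perturbation_labels=list(groups),
        embedding=np.vstack(rows),
        provenance="logreg",
    )


def cluster_space(
    ds: PerturbationDataset,
    method: str = "kmeans",
    representation: str = "X",
    groupby: str = "perturbation",
    seed: int = 0,
    k: int = 2,
    eps: float = 0.5,
    min_samples: int = 5,
) -> ClusterSpaceResult:
    """Cluster cells and score overlap with the perturbation labels."""
    rep = as_dense(select_representation(ds, representation))
    if method == "kmeans":
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > rep.shape[0]:
            raise ValueError(f"k={k} exceeds number of cells ({rep.shape[0]})")
        ids = KMeans(n_clusters=k, random_state=seed, n_init=10).fit_predict(rep)
        params = {"k": k, "seed": seed}
    elif method == "dbscan":
        if eps <= 0 or min_samples < 1:
            raise ValueError("dbscan requires eps > 0 and min_samples >= 1")
        ids = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(rep)
        params = {"eps": eps, "min_samples": min_samples}
    else:
        raise ValueError(f"unknown method '{method}'")
    truth = ds.obs[groupby].to_numpy(dtype=object).astype(str)
    return ClusterSpaceResult(
        cluster_ids=ids,
        method=method,
        params=params,
        ari=float(adjusted_rand_score(truth, ids)),
        nmi=float(normalized_mutual_info_score(truth, ids)),
    )


def label_transfer(
    ds: PerturbationDataset,
    labeled_mask,
    labels,
    k: int = 15,
    representation: str = "X",
) -> LabelTransferResult:
    """Connectivity-weighted k-NN majority vote with entropy uncertainty.

    For each unlabeled cell the k nearest labeled cells (Euclidean, in
    ``representation``) vote with Gaussian-kernel weights
    ``exp(-d^2 / (2 bw^2))`` where ``bw`` is that cell's mean neighbor
    distance. The predicted label is the argmax of the normalized weighted
    label distribution (ties broken lexicographically) and the uncertainty
    is its Shannon entropy in bits: 0 for a unanimous neighborhood, 1 bit
    for an exactly balanced two-label split.

    Labeled cells keep their own label with uncertainty 0.
    """
    labeled_mask = np.asarray(labeled_mask, dtype=bool)
    labels = np.asarray(labels, dtype=object)
    if labeled_mask.sum() == 0 or (~labeled_mask).sum() == 0:
        raise ValueError("need at least 1 labeled and 1 unlabeled cell")
    if k > labeled_mask.sum():
        raise ValueError(f"k={k} exceeds number of labeled cells")
    rep = as_dense(select_representation(ds, representation))

    label_values = np.array(sorted(set(map(str, labels[labeled_mask]))))
    label_index = {l: i for i, l in enumerate(label_values)}

    nn = NearestNeighbors(n_neighbors=k, algorithm="brute").fit(rep[labeled_mask])
    dist, idx = nn.kneighbors(rep[~labeled_mask])
    neighbor_labels = labels[labeled_mask][idx].astype(str)

    n_unlab = dist.shape[0]
    predicted = np.array(labels, dtype=object)
    uncertainty = np.zeros(len(labels))
    for i, row in enumerate(np.flatnonzero(~labeled_mask)):
        bw = dist[i].mean()
        w = np.exp(-(dist[i] ** 2) / (2 * bw**2)) if bw > 0 else np.ones(k)
        total = w.sum()
        if total <= 0:  # unreachable with Gaussian weights; guarded anyway
            raise ValueError(f"zero total neighbor weight for cell {row}")
        p = np.zeros(len(label_values))
        for wj, lj in zip(w, neighbor_labels[i]):
            p[label_index[lj]] += wj
        p /= total
        nzp = p[p > 0]
        predicted[row] = label_values[int(np.argmax(p))]
        uncertainty[row] = float(-(nzp * np.log2(nzp)).sum())
    return LabelTransferResult(predicted=predicted, uncertainty=uncertainty)
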
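"""Shared data model for perturbation screens.

A :class:`PerturbationDataset` holds a cells x features expression matrix
(raw counts or normalized values, dense or sparse) together with per-cell
annotations (perturbation label, optional split/batch label, anything else),
named low-dimensional representations (cells x d) and named layers
(cells x features, e.g. a perturbation signature).

Control cells are not baked into the dataset: every operation that needs
them takes a ``control_label`` argument and derives the control mask on the
fly, so the same dataset can be analysed against different references.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "PerturbationDataset",
    "GroupSummary",
    "DistanceResult",
    "PermutationTestResult",
    "as_dense",
    "validate_dataset",
    "split_groups",
    "select_representation",
    "summarize_group",
]

PERTURBATION_KEY = "perturbation"


def as_dense(X) -> np.ndarray:
    """Return ``X`` as a dense 2-d float array (no copy if already one)."""
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=float)
    return np.asarray(X, dtype=float)


@dataclass
class PerturbationDataset:
    """Cells x features matrix plus per-cell annotations.

    Parameters
    ----------
    matrix
        cells x features, dense ndarray or scipy sparse.
    obs
        Per-cell annotation table indexed by cell id. Must contain a
        ``"perturbation"`` column; may carry a split/batch column and any
        other per-cell metadata.
    feature_ids
        Feature (gene) names, one per matrix column.
    representations
        Named cells x d matrices (e.g. ``"pca"``).
    layers
        Named cells x features matrices (e.g. ``"signature"``).
    """

    matrix: object
    obs: pd.DataFrame
    feature_ids: list
    representations: dict = field(default_factory=dict)
    layers: dict = field(default_factory=dict)

    def __post_init__(self):
        self.obs = pd.DataFrame(self.obs)
        self.feature_ids = list(self.feature_ids)

    # -- convenience accessors -------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]

    @property
    def cell_ids(self) -> list:
        return list(self.obs.index.astype(str))

    @property
    def perturbation_label(self) -> np.ndarray:
        return self.obs[PERTURBATION_KEY].to_numpy(dtype=object)

    def control_mask(self, control_label: str) -> np.ndarray:
        """Boolean mask of cells carrying ``control_label``."""
        return self.perturbation_label == control_label

    def X_dense(self) -> np.ndarray:
        return as_dense(self.matrix)


@dataclass
class GroupSummary:
    """Per-feature mean and unbiased variance of one group of cells."""

    mean: np.ndarray
    variance: np.ndarray
    n_cells: int


@dataclass
class DistanceResult:
    """Group x group matrix of one named metric."""

    group_labels: list
    values: np.ndarray
    metric_id: str
    symmetric: bool
    representation_used: str = "X"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.group_labels, columns=self.group_labels
        )


@dataclass
class PermutationTestResult:
    """Monte-Carlo permutation test of one group-vs-control distance."""

    metric_id: str
    observed: float
    null_draws: np.ndarray
    p_value: float
    alpha: float
    significant: bool
    n_perm: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "metric": self.metric_id,
            "observed": float(self.observed),
            "p_value": float(self.p_value),
            "alpha": float(self.alpha),
            "significant": bool(self.significant),
            "n_perm": int(self.n_perm),
            "seed": int(self.seed),
        }


def validate_dataset(ds: PerturbationDataset) -> list:
    """Check the dataset invariants; return one message per violation.

    Never raises and never mutates ``ds``: callers decide what to do with
    the report (the CLI refuses to run on a non-empty one).
    """
    violations = []
    n_cells, n_features = ds.matrix.shape

    if len(ds.obs) != n_cells:
        violations.append(
            f"obs has {len(ds.obs)} rows but matrix has {n_cells} cells"
        )
    if len(ds.feature_ids) != n_features:
        violations.append(
            f"{len(ds.feature_ids)} feature_ids but matrix has "
            f"{n_features} columns"
        )
    ids = pd.Index(ds.obs.index.astype(str))
    if ids.has_duplicates:
        dups = sorted(set(ids[ids.duplicated()]))
        violations.append(f"duplicated cell_id(s): {dups}")
    feats = pd.Index(ds.feature_ids)
    if feats.has_duplicates:
        dups = sorted(set(feats[feats.duplicated()]))
        violations.append(f"duplicated feature_id(s): {dups}")

    if PERTURBATION_KEY not in ds.obs.columns:
        violations.append(f"obs lacks required column '{PERTURBATION_KEY}'")
    else:
        labels = ds.obs[PERTURBATION_KEY]
        if labels.isna().any() or (labels.astype(str) == "").any():
            violations.append("perturbation labels contain empty values")

    for name, rep in ds.representations.items():
        if rep.shape[0] != n_cells:
            violations.append(
                f"representation '{name}' has {rep.shape[0]} rows, "
                f"expected {n_cells}"
            )
    for name, layer in ds.layers.items():
        if layer.shape[0] != n_cells:
            violations.append(
                f"layer '{name}' has {layer.shape[0]} rows, expected {n_cells}"
            )
    return violations


def split_groups(ds: PerturbationDataset, groupby: str = PERTURBATION_KEY) -> dict:
    """Partition cell indices by a per-cell annotation.

    Returns a dict mapping each label to a sorted integer index array;
    labels are returned in lexicographic order so downstream group matrices
    are reproducible.
    """
    if groupby not in ds.obs.columns:
        available = ", ".join(map(str, ds.obs.columns))
        raise KeyError(
            f"unknown annotation '{groupby}'; available: {available}"
        )
    labels = ds.obs[groupby].to_numpy(dtype=object)
    out = {}
    for label in sorted(map(str, pd.unique(labels))):
        out[label] = np.flatnonzero(labels.astype(str) == label)
    return out


def select_representation(ds: PerturbationDataset, name: str = "X"):
    """Fetch the main matrix (``"X"``), a stored representation, or a layer."""
    if name == "X":
        return ds.matrix
    if name in ds.representations:
        return ds.representations[name]
    if name in ds.layers:
        return ds.layers[name]
    stored = ["X"] + list(ds.representations) + list(ds.layers)
    raise KeyError(f"unknown representation '{name}'; stored: {stored}")


def summarize_group(X) -> GroupSummary:
    """Per-feature mean and unbiased (n-1) variance of a group matrix.

    Variance is defined as 0 for a single-cell group. Dense and sparse
    inputs give identical results.
    """
    if X.shape[0] < 1:
        raise ValueError("cannot summarize an empty group")
    n = X.shape[0]
    if sp.issparse(X):
        mean = np.asarray(X.mean(axis=0)).ravel()
        if n == 1:
            var = np.zeros_like(mean)
        else:
            sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
            var = (sq - mean**2) * n / (n - 1)
            var = np.maximum(var, 0.0)
    else:
        Xd = np.asarray(X, dtype=float)
        mean = Xd.mean(axis=0)
        var = np.zeros_like(mean) if n == 1 else Xd.var(axis=0, ddof=1)
    return GroupSummary(mean=mean, variance=var, n_cells=n)
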
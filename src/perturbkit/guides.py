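"""Guide-RNA-to-cell assignment for pooled CRISPR screens.

Two assignment strategies:

* :func:`assign_by_threshold` — each cell receives its most-expressed guide
  if that guide's count strictly exceeds a user threshold; suited to clean
  low-MOI screens.
* :func:`assign_mixture_model` — per guide, cells with non-zero counts are
  modelled in log2 space as a mixture of a low background population and a
  high signal population; a cell is positive for a guide when its posterior
  responsibility for the high component exceeds 0.5. Cells positive for
  1..max_assignments guides are "assigned"; for more, "multiple"; for none,
  "negative". Zero-count cells are always negative for that guide.

The background component is by default a Poisson on raw counts (its density
evaluated at the observed integer counts) against a Gaussian signal on log2
counts; ``method="gaussian"`` fits two Gaussians in log2 space instead. At
realistic background/signal separation the two are interchangeable.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats

__all__ = [
    "GuideCountMatrix",
    "GuideMixtureFit",
    "GuideAssignment",
    "assign_by_threshold",
    "fit_guide_mixture",
    "assign_mixture_model",
    "write_assignment_tsv",
]

MAX_ASSIGNMENTS_DEFAULT = 5


@dataclass
class GuideCountMatrix:
    """Cells x guides non-negative integer counts."""

    counts: object  # dense or sparse
    cell_ids: list
    guide_ids: list

    def __post_init__(self):
        self.cell_ids = list(map(str, self.cell_ids))
        self.guide_ids = list(map(str, self.guide_ids))
        n, g = self.counts.shape
        if n != len(self.cell_ids) or g != len(self.guide_ids):
            raise ValueError("counts shape inconsistent with id lists")
        dense = self.dense()
        if dense.min() < 0 or not np.allclose(dense, np.round(dense)):
            raise ValueError("guide counts must be non-negative integers")

    def dense(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)


@dataclass
class GuideMixtureFit:
    """Two-component mixture fitted to one guide's non-zero log2 counts."""

    guide_id: str
    method: str  # "poisson_gaussian" or "gaussian"
    converged: bool
    skipped: bool
    skip_reason: str = ""
    weight_background: float = np.nan
    weight_signal: float = np.nan
    background_rate: float = np.nan       # Poisson rate on counts
    background_log2_mean: float = np.nan  # Gaussian fallback
    background_log2_sd: float = np.nan
    signal_log2_mean: float = np.nan
    signal_log2_sd: float = np.nan
    n_iter: int = 0


@dataclass
class GuideAssignment:
    """Per-cell assignment result plus per-guide mixture fits."""

    cell_ids: list
    assigned: list                  # list of guide-id lists ([] if none kept)
    status: np.ndarray              # "assigned" | "multiple" | "negative"
    fits: dict = field(default_factory=dict)        # guide_id -> GuideMixtureFit
    positive: object = None         # cells x guides boolean positivity (mixture)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "status": self.status,
                "assigned_guides": [";".join(g) for g in self.assigned],
            }
        )


def assign_by_threshold(g: GuideCountMatrix, min_count: int = 0) -> GuideAssignment:
    """Assign each cell its most-expressed guide if count > min_count.

    Strict inequality; ties broken by the lowest guide index; at most one
    guide per cell, so status is either "assigned" or "negative".
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    counts = g.dense()
    best = counts.argmax(axis=1)  # argmax takes the first maximum: lowest index
    best_counts = counts[np.arange(counts.shape[0]), best]
    positive = best_counts > min_count
    assigned = [
        [g.guide_ids[j]] if ok else [] for j, ok in zip(best, positive)
    ]
    status = np.where(positive, "assigned", "negative").astype(object)
    return GuideAssignment(
        cell_ids=list(g.cell_ids), assigned=assigned, status=status
    )


def fit_guide_mixture(
    counts,
    guide_id: str = "",
    method: str = "poisson_gaussian",
    min_positive_cells: int = 10,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
):
    """Fit the two-population mixture for a single guide.

    Parameters
    ----------
    counts
        Non-negative integer counts of this guide across all cells.
    method
        "poisson_gaussian" (default): Poisson background on counts,
        Gaussian signal on log2 counts. "gaussian": two Gaussians in log2
        space.

    Returns
    -------
    (GuideMixtureFit, positive_flags)
        ``positive_flags`` marks cells whose posterior responsibility for
        the signal component exceeds 0.5; zero-count cells are always
        negative.
    """
    counts = np.asarray(counts, dtype=float).ravel()
    if counts.min() < 0 or not np.allclose(counts, np.round(counts)):
        raise ValueError("guide counts must be non-negative integers")
    positive_flags = np.zeros(counts.shape[0], dtype=bool)
    nz_mask = counts > 0
    nz = counts[nz_mask]

    def skipped(reason):
        warnings.warn(f"guide '{guide_id}' skipped: {reason}")
        return (
            GuideMixtureFit(
                guide_id=guide_id, method=method, converged=False,
                skipped=True, skip_reason=reason,
            ),
            positive_flags,
        )

    if nz.size < min_positive_cells:
        return skipped(
            f"only {nz.size} cells with non-zero counts "
            f"(needs >= {min_positive_cells})"
        )
    if np.unique(nz).size < 2:
        return skipped("fewer than 2 distinct non-zero values")

    log2_nz = np.log2(nz)

    # k-means-style initialization on log2 counts: split at the midrange,
    # refine once by nearest-center reassignment
    centers = np.array([log2_nz.min(), log2_nz.max()], dtype=float)
    for _ in range(10):
        assign_hi = np.abs(log2_nz - centers[1]) < np.abs(log2_nz - centers[0])
        if assign_hi.all() or (~assign_hi).all():
            break
        new = np.array([log2_nz[~assign_hi].mean(), log2_nz[assign_hi].mean()])
        if np.allclose(new, centers):
            centers = new
            break
        centers = new
    lo_mask = ~assign_hi
    if lo_mask.sum() == 0 or assign_hi.sum() == 0:
        # no separation at all; treat everything as one (signal) population
        lo_mask = log2_nz < np.median(log2_nz)
        assign_hi = ~lo_mask

    w_b = max(lo_mask.mean(), 1e-3)
    w_s = 1.0 - w_b
    lam = max(nz[lo_mask].mean() if lo_mask.any() else 1.0, 1e-3)
    mu_b = log2_nz[lo_mask].mean() if lo_mask.any() else log2_nz.min()
    sd_b = max(log2_nz[lo_mask].std(), 0.1)
    mu_s = log2_nz[assign_hi].mean()
    sd_s = max(log2_nz[assign_hi].std(), 0.1)

    def background_logpdf(lam_, mu_b_, sd_b_):
        if method == "poisson_gaussian":
            return scipy.stats.poisson.logpmf(nz.astype(int), lam_)
        return scipy.stats.norm.logpdf(log2_nz, mu_b_, sd_b_)

    prev_ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        log_b = np.log(w_b) + background_logpdf(lam, mu_b, sd_b)
        log_s = np.log(w_s) + scipy.stats.norm.logpdf(log2_nz, mu_s, sd_s)
        log_norm = np.logaddexp(log_b, log_s)
        resp_s = np.exp(log_s - log_norm)
        ll = float(log_norm.sum())

        # M step
        w_s = float(np.clip(resp_s.mean(), 1e-6, 1 - 1e-6))
        w_b = 1.0 - w_s
        resp_b = 1.0 - resp_s
        sb = resp_b.sum()
        ss = resp_s.sum()
        if sb > 0:
            lam = max(float((resp_b * nz).sum() / sb), 1e-3)
            mu_b = float((resp_b * log2_nz).sum() / sb)
            sd_b = max(
                float(np.sqrt((resp_b * (log2_nz - mu_b) ** 2).sum() / sb)), 0.05
            )
        if ss > 0:
            mu_s = float((resp_s * log2_nz).sum() / ss)
            sd_s = max(
                float(np.sqrt((resp_s * (log2_nz - mu_s) ** 2).sum() / ss)), 0.05
            )
        if abs(ll - prev_ll) < tol * max(1.0, abs(prev_ll)):
            converged = True
            break
        prev_ll = ll

    # the "signal" component is the one with the higher log2 mean
    bg_mean_log2 = np.log2(max(lam, 1e-3)) if method == "poisson_gaussian" else mu_b
    if mu_s < bg_mean_log2:
        # swapped during EM: relabel so positives follow the higher mode
        resp_s = 1.0 - resp_s

    positive_flags[nz_mask] = resp_s > 0.5  # exactly 0.5 stays negative
    fit = GuideMixtureFit(
        guide_id=guide_id,
        method=method,
        converged=converged,
        skipped=False,
        weight_background=w_b,
        weight_signal=w_s,
        background_rate=lam if method == "poisson_gaussian" else np.nan,
        background_log2_mean=mu_b,
        background_log2_sd=sd_b,
        signal_log2_mean=mu_s,
        signal_log2_sd=sd_s,
        n_iter=n_iter,
    )
    return fit, positive_flags


def assign_mixture_model(
    g: GuideCountMatrix,
    max_assignments: int = MAX_ASSIGNMENTS_DEFAULT,
    method: str = "poisson_gaussian",
    seed: int = 0,
    **fit_kwargs,
) -> GuideAssignment:
    """Mixture-model guide assignment across all guides.

    Cells positive for 1..max_assignments guides get those guides with
    status "assigned"; cells positive for more are "multiple" (their
    per-guide positivity remains inspectable but no guides are recorded);
    cells positive for none are "negative". Guides that cannot be fit are
    skipped with a warning, never aborting the run.
    """
    if max_assignments < 1:
        raise ValueError("max_assignments must be >= 1")
    counts = g.dense()
    n_cells, n_guides = counts.shape
    positive = np.zeros((n_cells, n_guides), dtype=bool)
    fits = {}
    for j, guide in enumerate(g.guide_ids):
        fit, flags = fit_guide_mixture(
            counts[:, j], guide_id=guide, method=method, seed=seed, **fit_kwargs
        )
        fits[guide] = fit
        positive[:, j] = flags

    n_pos = positive.sum(axis=1)
    status = np.empty(n_cells, dtype=object)
    assigned = []
    for i in range(n_cells):
        if n_pos[i] == 0:
            status[i] = "negative"
            assigned.append([])
        elif n_pos[i] > max_assignments:
            status[i] = "multiple"
            assigned.append([])
        else:
            status[i] = "assigned"
            assigned.append([g.guide_ids[j] for j in np.flatnonzero(positive[i])])
    return GuideAssignment(
        cell_ids=list(g.cell_ids),
        assigned=assigned,
        status=status,
        fits=fits,
        positive=positive,
    )


def write_assignment_tsv(assignment: GuideAssignment, path) -> None:
    """Write assignments as TSV: cell_id, status, assigned_guides."""
    assignment.to_frame().to_csv(path, sep="\t", index=False)
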
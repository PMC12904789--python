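"""Synthetic perturbation screens with known ground truth.

The expression generator draws control cells from per-gene negative
binomial distributions (mean mu_g, dispersion theta, so variance
mu + mu^2/theta) with lognormal per-cell library-size factors. Each
perturbation multiplies its affected genes' means by exp(effect_size)
(natural-log fold change); a fraction of targeted cells ("escapees") are
drawn from the control model but keep the targeted label, emulating cells
that escaped CRISPR perturbation. A log1p depth-normalized layer is
emitted alongside the raw counts.

The guide generator emulates low- and high-MOI CRISPR screens: each cell's
true guide(s) receive counts 2^Normal(signal_log2_mean, sd) and every guide
additionally picks up Poisson(background_rate) ambient contamination.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import PerturbationDataset
from .guides import GuideCountMatrix

__all__ = [
    "SimulationTruth",
    "simulate_expression",
    "simulate_guides",
    "simulate_prediction_pair",
    "CONTROL_LABEL",
]

CONTROL_LABEL = "control"


@dataclass
class SimulationTruth:
    """Ground truth of one simulated dataset."""

    true_perturbation: np.ndarray | None = None
    true_guides: list | None = None
    escape_flag: np.ndarray | None = None
    affected_genes: dict = field(default_factory=dict)
    effect_sizes: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    seed: int = 0


def _nb_counts(rng, mu, theta):
    """NB draws with mean mu (array broadcastable) and dispersion theta."""
    mu = np.asarray(mu, dtype=float)
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p)


def simulate_expression(
    n_groups: int = 3,
    cells_per_group: int = 100,
    n_genes: int = 200,
    n_affected_genes: int = 20,
    effect_size: float = 1.0,
    dispersion: float = 2.0,
    base_mean: float = 5.0,
    escape_rate: float = 0.0,
    library_size_cv: float = 0.1,
    n_control_cells: int | None = None,
    seed: int = 0,
):
    """Simulate an expression screen with ``n_groups`` perturbations + control.

    Returns ``(PerturbationDataset, SimulationTruth)``. The dataset carries
    raw counts in ``matrix``, a ``"lognorm"`` layer (log1p of
    median-depth-scaled counts), a ``"split"`` obs column (two pseudo-lanes,
    each containing controls, so split-referenced signatures are testable)
    and per-cell ``perturbation`` labels with ``"control"`` for controls.

    Defaults describe a modest CRISPR screen: 100 cells per condition,
    200 genes with NB(mu=5, theta=2) baseline counts, 20 affected genes per
    perturbation shifted by a natural-log fold change of 1, 10% library-size
    CV and no escapees unless requested.
    """
    if min(n_groups, cells_per_group, n_genes, n_affected_genes) < 1:
        raise ValueError("all size parameters must be positive")
    if n_affected_genes > n_genes:
        raise ValueError("n_affected_genes cannot exceed n_genes")
    if not (0 <= escape_rate < 1):
        raise ValueError("escape_rate must be in [0, 1)")
    if effect_size < 0:
        raise ValueError("effect_size is a magnitude; use >= 0")
    rng = np.random.default_rng(seed)

    if n_control_cells is None:
        n_control_cells = cells_per_group
    # per-gene baseline means, lognormal around base_mean for heterogeneity
    mu_g = base_mean * rng.lognormal(mean=0.0, sigma=0.25, size=n_genes)

    group_names = [f"pert{g + 1}" for g in range(n_groups)]
    labels = [CONTROL_LABEL] * n_control_cells
    for name in group_names:
        labels += [name] * cells_per_group
    labels = np.array(labels, dtype=object)
    n_cells = len(labels)

    affected = {}
    effects = {}
    escape = np.zeros(n_cells, dtype=bool)
    counts = np.zeros((n_cells, n_genes), dtype=np.int64)

    # controls
    counts[:n_control_cells] = _nb_counts(
        rng, np.tile(mu_g, (n_control_cells, 1)), dispersion
    )
    # perturbations
    offset = n_control_cells
    for name in group_names:
        genes = rng.choice(n_genes, size=n_affected_genes, replace=False)
        genes.sort()
        affected[name] = genes
        effects[name] = effect_size
        mu_p = mu_g.copy()
        mu_p[genes] = mu_p[genes] * np.exp(effect_size)
        esc = rng.random(cells_per_group) < escape_rate
        for i in range(cells_per_group):
            mu_row = mu_g if esc[i] else mu_p
            counts[offset + i] = _nb_counts(rng, mu_row, dispersion)
        escape[offset : offset + cells_per_group] = esc
        offset += cells_per_group

    # per-cell library-size factor, lognormal with the requested CV
    if library_size_cv > 0:
        sigma = np.sqrt(np.log(1.0 + library_size_cv**2))
        factors = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=n_cells)
        counts = rng.poisson(counts * factors[:, None])

    depth = counts.sum(axis=1).astype(float)
    depth[depth == 0] = 1.0
    lognorm = np.log1p(counts / depth[:, None] * np.median(depth))

    obs = pd.DataFrame(
        {
            "perturbation": labels,
            "split": np.where(np.arange(n_cells) % 2 == 0, "lane1", "lane2"),
        },
        index=[f"cell{i}" for i in range(n_cells)],
    )
    ds = PerturbationDataset(
        matrix=counts,
        obs=obs,
        feature_ids=[f"gene{j}" for j in range(n_genes)],
        layers={"lognorm": lognorm},
    )
    truth = SimulationTruth(
        true_perturbation=labels.copy(),
        escape_flag=escape,
        affected_genes=affected,
        effect_sizes=effects,
        params={
            "n_groups": n_groups,
            "cells_per_group": cells_per_group,
            "n_genes": n_genes,
            "n_affected_genes": n_affected_genes,
            "effect_size": effect_size,
            "dispersion": dispersion,
            "base_mean": base_mean,
            "escape_rate": escape_rate,
            "library_size_cv": library_size_cv,
            "n_control_cells": n_control_cells,
            "mu_g": mu_g,
        },
        seed=seed,
    )
    return ds, truth


def simulate_guides(
    n_cells: int = 1000,
    n_guides: int = 20,
    moi_mode: str = "low",
    background_rate: float = 0.3,
    signal_log2_mean: float = 6.0,
    signal_log2_sd: float = 0.5,
    high_moi_mean: float = 3.0,
    seed: int = 0,
):
    """Simulate a cells x guides count matrix with known true guides.

    Low MOI draws exactly one true guide per cell; high MOI draws a
    Poisson(high_moi_mean) number (at least 1). True guides get counts
    ``round(2^Normal(signal_log2_mean, signal_log2_sd))``; all guides then
    receive Poisson(background_rate) ambient counts.
    """
    if background_rate < 0:
        raise ValueError("background_rate must be >= 0")
    if not np.isfinite([signal_log2_mean, signal_log2_sd]).all():
        raise ValueError("signal parameters must be finite")
    if moi_mode not in ("low", "high"):
        raise ValueError("moi_mode must be 'low' or 'high'")
    rng = np.random.default_rng(seed)

    counts = rng.poisson(background_rate, size=(n_cells, n_guides)).astype(np.int64)
    true_guides = []
    for i in range(n_cells):
        if moi_mode == "low":
            n_true = 1
        else:
            n_true = max(1, rng.poisson(high_moi_mean))
            n_true = min(n_true, n_guides)
        guides = rng.choice(n_guides, size=n_true, replace=False)
        sig = np.round(
            2.0 ** rng.normal(signal_log2_mean, signal_log2_sd, size=n_true)
        ).astype(np.int64)
        counts[i, guides] += np.maximum(sig, 1)
        true_guides.append([f"guide{g}" for g in sorted(guides)])

    g = GuideCountMatrix(
        counts=counts,
        cell_ids=[f"cell{i}" for i in range(n_cells)],
        guide_ids=[f"guide{j}" for j in range(n_guides)],
    )
    truth = SimulationTruth(
        true_guides=true_guides,
        params={
            "n_cells": n_cells,
            "n_guides": n_guides,
            "moi_mode": moi_mode,
            "background_rate": background_rate,
            "signal_log2_mean": signal_log2_mean,
            "signal_log2_sd": signal_log2_sd,
        },
        seed=seed,
    )
    return g, truth


def simulate_prediction_pair(
    prediction_quality: float = 1.0,
    n_cells: int = 200,
    n_control_cells: int = 2000,
    n_genes: int = 300,
    effect_sd: float = 1.0,
    dispersion: float = 2.0,
    base_mean: float = 5.0,
    seed: int = 0,
):
    """Control / real-perturbed / predicted-perturbed matrix triple.

    The perturbation shifts every gene by its own log-fold change drawn
    from Normal(0, effect_sd) — a spectrum of up- and down-regulation, as
    real perturbations produce, which is what makes a gene *ranking*
    meaningful. The predicted matrix is drawn from the same model with all
    effects scaled by ``prediction_quality``: quality 0 is a null
    prediction (fresh control resample), quality 1 a fresh resample of the
    true perturbed model. Returns ``(control, perturbed, predicted,
    truth)``.

    The control group is 10x the perturbed group by default, as in typical
    screens where controls dominate. This also matters statistically: both
    differential-expression rankings share the control matrix, so shared
    control sampling noise induces a positive ranking correlation even for
    a null prediction; a large control group keeps that floor small.
    """
    if not (0 <= prediction_quality <= 1):
        raise ValueError("prediction_quality must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mu_g = base_mean * rng.lognormal(mean=0.0, sigma=0.25, size=n_genes)
    effects = rng.normal(0.0, effect_sd, size=n_genes)

    mu_pert = mu_g * np.exp(effects)
    mu_pred = mu_g * np.exp(prediction_quality * effects)

    control = _nb_counts(rng, np.tile(mu_g, (n_control_cells, 1)), dispersion)
    perturbed = _nb_counts(rng, np.tile(mu_pert, (n_cells, 1)), dispersion)
    predicted = _nb_counts(rng, np.tile(mu_pred, (n_cells, 1)), dispersion)
    truth = SimulationTruth(
        affected_genes={"pert": np.arange(n_genes)},
        effect_sizes={"pert": effects},
        params={
            "prediction_quality": prediction_quality,
            "n_cells": n_cells,
            "n_control_cells": n_control_cells,
            "n_genes": n_genes,
            "effect_sd": effect_sd,
        },
        seed=seed,
    )
    return control, perturbed, predicted, truth
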
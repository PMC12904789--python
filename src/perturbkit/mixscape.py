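"""Perturbation signatures and KO/NP classification of targeted cells.

CRISPR cutting is not uniformly effective: some targeted cells escape
perturbation (e.g. through in-frame mutations) and behave like controls.
The workflow here mirrors the Mixscape idea:

1. :func:`perturbation_signature` removes cell-intrinsic state by
   subtracting a control reference from every cell — either the mean of the
   k nearest control cells in a low-dimensional representation (``nn``
   mode) or the mean of all control cells in the cell's split/batch
   (``split_by`` mode).
2. :func:`mixscape_classify` scores each targeted cell by projecting its
   signature onto the direction separating the current KO-set mean from the
   control mean (restricted to the most differential features), fits a
   two-Gaussian model on the scores with the null component anchored on
   control cells, and iterates posterior > threshold reassignment until the
   KO/NP split stabilises. Cells below threshold are NP (escaped).
3. :func:`lda_projection` embeds cells with linear discriminant analysis
   fit on KO + control cells, for visualising perturbation similarity.

CRISPRi/CRISPRa inputs are accepted (a logged caveat notes the weaker
escape model for those modalities).
"""

from __future__ import annotations

import logging
import warnings

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import NearestNeighbors

from .core import PerturbationDataset, as_dense, select_representation

__all__ = [
    "SignatureLayer",
    "MixscapeResult",
    "perturbation_signature",
    "mixscape_classify",
    "lda_projection",
    "write_classification_tsv",
]

logger = logging.getLogger(__name__)


@dataclass
class SignatureLayer:
    """Cells x features perturbation signature (expression minus reference)."""

    values: np.ndarray
    reference_mode: str  # "nn" or "split_by"
    k: int
    representation_used: str


@dataclass
class MixscapeResult:
    """Per-cell KO/NP/control classes with KO posteriors."""

    cell_ids: list
    classes: np.ndarray            # "control" | "KO" | "NP"
    posterior: np.ndarray          # P(KO); NaN for control cells
    target_params: dict            # target -> fitted component parameters
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "class": self.classes,
                "posterior": self.posterior,
            }
        )


def perturbation_signature(
    ds: PerturbationDataset,
    control_label: str,
    mode: str = "nn",
    k: int = 20,
    representation: str = "X",
    split_key: str | None = None,
    layer: str | None = None,
) -> SignatureLayer:
    """Per-cell expression minus a control reference.

    ``nn`` mode: the reference for each cell is the mean expression of its
    k nearest control cells, found by Euclidean distance in
    ``representation`` (exact brute-force search). ``split_by`` mode: the
    reference is the mean of all control cells in the cell's split (e.g.
    GEM group / lane), requiring ``split_key``. ``layer`` selects the
    expression source (default: the main matrix); normalized expression is
    the usual choice.
    """
    X = as_dense(ds.layers[layer]) if layer is not None else ds.X_dense()
    ctrl = ds.control_mask(control_label)
    if not ctrl.any():
        raise ValueError(f"no cells carry control label '{control_label}'")

    if mode == "nn":
        rep = as_dense(select_representation(ds, representation))
        n_ctrl = int(ctrl.sum())
        if k > n_ctrl:
            raise ValueError(f"k={k} exceeds number of control cells ({n_ctrl})")
        nn = NearestNeighbors(n_neighbors=k, algorithm="brute").fit(rep[ctrl])
        _, idx = nn.kneighbors(rep)
        ctrl_expr = X[ctrl]
        reference = ctrl_expr[idx].mean(axis=1)
    elif mode == "split_by":
        if split_key is None:
            raise ValueError("split_by mode requires split_key")
        if split_key not in ds.obs.columns:
            raise KeyError(f"unknown split annotation '{split_key}'")
        splits = ds.obs[split_key].to_numpy(dtype=object)
        reference = np.empty_like(X)
        for split in pd.unique(splits):
            in_split = splits == split
            split_ctrl = in_split & ctrl
            if not split_ctrl.any():
                raise ValueError(f"split '{split}' contains no control cells")
            reference[in_split] = X[split_ctrl].mean(axis=0)
    else:
        raise ValueError(f"unknown mode '{mode}' (expected 'nn' or 'split_by')")

    return SignatureLayer(
        values=X - reference,
        reference_mode=mode,
        k=k if mode == "nn" else 0,
        representation_used=representation if mode == "nn" else "",
    )


def _anchored_two_gaussian_em(
    scores, mu0: float, sd0: float, min_sd: float,
    max_iter: int = 200, tol: float = 1e-8,
):
    """EM for a two-Gaussian mixture with the null component fixed.

    The null (control/NP) component's mean and sd are held at the control
    estimates; the KO component's mean, sd and the mixture weight are free.
    Returns ``(posterior_of_KO, params)`` or ``(None-posterior, None)``
    when the two-component model does not improve the BIC over a single
    control-shaped Gaussian — i.e. the target group does not separate.
    """
    n = len(scores)
    w1 = 0.5
    upper = scores[scores > np.median(scores)]
    mu1 = upper.mean() if upper.size else scores.mean()
    sd1 = max(scores.std(), min_sd)
    ll = -np.inf
    resp1 = np.full(n, 0.5)
    for _ in range(max_iter):
        log_p0 = np.log(1 - w1) + scipy.stats.norm.logpdf(scores, mu0, sd0)
        log_p1 = np.log(w1) + scipy.stats.norm.logpdf(scores, mu1, sd1)
        log_norm = np.logaddexp(log_p0, log_p1)
        resp1 = np.exp(log_p1 - log_norm)
        new_ll = float(log_norm.sum())
        w1 = float(np.clip(resp1.mean(), 1e-3, 1 - 1e-3))
        s1 = resp1.sum()
        if s1 > 0:
            mu1 = float((resp1 * scores).sum() / s1)
            sd1 = max(
                float(np.sqrt((resp1 * (scores - mu1) ** 2).sum() / s1)), min_sd
            )
        if abs(new_ll - ll) < tol * max(1.0, abs(ll)):
            ll = new_ll
            break
        ll = new_ll

    # does the extra component earn its 3 parameters?
    ll_one = float(scipy.stats.norm.logpdf(scores, mu0, sd0).sum())
    bic_two = -2.0 * ll + 3.0 * np.log(n)
    bic_one = -2.0 * ll_one
    if bic_two >= bic_one or mu1 <= mu0:
        return resp1, None
    params = {
        "mu_null": float(mu0),
        "sd_null": float(sd0),
        "mu_ko": float(mu1),
        "sd_ko": float(sd1),
        "weight_ko": float(w1),
    }
    return resp1, params


def _top_feature_mask(
    sig_target, sig_control, n_top: int, de_alpha: float = 0.05
) -> np.ndarray:
    """Top differential signature features between target and control.

    Candidates must pass a Benjamini-Hochberg-adjusted Welch t-test at
    ``de_alpha``; ranking the candidates by |t| then takes the strongest
    ``n_top``. The significance gate prevents magnitude-only selection from
    manufacturing separation out of noise when the target group actually
    matches the controls (the all-NP case).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        res = scipy.stats.ttest_ind(
            sig_target, sig_control, axis=0, equal_var=False
        )
    t = np.where(np.isfinite(res.statistic), res.statistic, 0.0)
    p = np.where(np.isfinite(res.pvalue), res.pvalue, 1.0)
    # Benjamini-Hochberg
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    candidates = adj < de_alpha
    mask = np.zeros(m, dtype=bool)
    if not candidates.any():
        return mask
    idx = np.flatnonzero(candidates)
    keep = idx[np.argsort(np.abs(t[idx]))[::-1][: min(n_top, idx.size)]]
    mask[keep] = True
    return mask


def mixscape_classify(
    ds: PerturbationDataset,
    control_label: str,
    signature: SignatureLayer | np.ndarray | str = "signature",
    threshold: float = 0.5,
    max_iter: int = 10,
    n_top_features: int = 100,
    de_alpha: float = 0.05,
    min_sd: float = 1e-6,
) -> MixscapeResult:
    """Classify targeted cells into KO (perturbed) vs NP (escaped).

    Control cells are always classed "control" with undefined (NaN)
    posterior. For every target group the iterative procedure runs until
    KO/NP assignments stop changing or ``max_iter`` is reached; a posterior
    exactly at ``threshold`` is NP (conservative). A target group whose
    cells all end below threshold is reported all-NP with a warning.
    """
    if isinstance(signature, str):
        sig = as_dense(ds.layers[signature]) if signature in ds.layers else None
        if sig is None:
            raise KeyError(f"no layer named '{signature}'")
    elif isinstance(signature, SignatureLayer):
        sig = signature.values
    else:
        sig = as_dense(signature)
    if sig.shape != ds.matrix.shape:
        raise ValueError("signature shape must match the dataset matrix")

    labels = ds.perturbation_label.astype(str)
    ctrl = ds.control_mask(control_label)
    n_cells = ds.n_cells
    classes = np.empty(n_cells, dtype=object)
    posterior = np.full(n_cells, np.nan)
    classes[ctrl] = "control"

    sig_ctrl = sig[ctrl]
    target_params = {}
    for target in sorted(set(labels[~ctrl])):
        cells = np.flatnonzero((labels == target) & ~ctrl)
        if len(cells) < 2:
            raise ValueError(f"target group '{target}' has fewer than 2 cells")
        sig_t = sig[cells]
        ko_mask = np.ones(len(cells), dtype=bool)  # start: everyone KO
        post_t = np.ones(len(cells))
        params = {}
        for _ in range(max_iter):
            if not ko_mask.any():
                break
            feat = _top_feature_mask(
                sig_t[ko_mask], sig_ctrl, n_top_features, de_alpha
            )
            if not feat.any():
                # no significantly differential feature: cannot separate
                ko_mask[:] = False
                post_t = np.zeros(len(cells))
                params = {}
                break
            direction = sig_t[ko_mask][:, feat].mean(axis=0) - sig_ctrl[
                :, feat
            ].mean(axis=0)
            norm = np.linalg.norm(direction)
            if norm == 0:
                ko_mask[:] = False
                break
            direction = direction / norm
            scores_t = sig_t[:, feat] @ direction
            scores_c = sig_ctrl[:, feat] @ direction

            # null component anchored on control cells; KO component free
            mu0, sd0 = scores_c.mean(), max(scores_c.std(), min_sd)
            post_t, params = _anchored_two_gaussian_em(
                scores_t, mu0, sd0, min_sd
            )
            if params is None:
                # two components do not beat one control-shaped Gaussian
                # (BIC): the target does not separate, everyone is NP
                ko_mask[:] = False
                post_t = np.zeros(len(cells))
                params = {"mu_null": float(mu0), "sd_null": float(sd0)}
                break
            new_ko = post_t > threshold  # exactly at threshold -> NP
            if np.array_equal(new_ko, ko_mask):
                ko_mask = new_ko
                break
            ko_mask = new_ko
        if not ko_mask.any():
            warnings.warn(
                f"target '{target}' never separated from control; all cells NP"
            )
        classes[cells] = np.where(ko_mask, "KO", "NP")
        posterior[cells] = post_t
        target_params[target] = params

    logger.info(
        "mixscape_classify: %d KO, %d NP, %d control cells "
        "(CRISPRi/CRISPRa inputs are valid only when escapees separate cleanly)",
        int((classes == "KO").sum()),
        int((classes == "NP").sum()),
        int(ctrl.sum()),
    )
    return MixscapeResult(
        cell_ids=ds.cell_ids,
        classes=classes,
        posterior=posterior,
        target_params=target_params,
        threshold=threshold,
    )


def lda_projection(
    signatures,
    labels,
    classes=None,
    n_components: int | None = None,
):
    """Linear-discriminant embedding of signatures by perturbation label.

    ``labels`` is the per-cell class used for the discriminant (the
    perturbation label, with control cells carrying the control label).
    When Mixscape ``classes`` are supplied, the axes are fit on KO and
    control cells only (NP escapees would blur the class structure); all
    cells, including NP, are then projected. ``n_components`` must be at
    most #classes - 1.
    """
    sig = as_dense(signatures)
    labels = np.asarray(labels, dtype=object)
    if classes is None:
        fit_mask = np.ones(len(labels), dtype=bool)
    else:
        fit_mask = np.asarray(classes, dtype=object) != "NP"
    fit_labels = labels[fit_mask].astype(str)
    uniq = np.unique(fit_labels)
    if uniq.size < 2:
        raise ValueError("LDA needs at least 2 classes among KO groups + control")
    max_comp = uniq.size - 1
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        raise ValueError(
            f"n_components={n_components} exceeds #classes-1 = {max_comp}"
        )
    lda = LinearDiscriminantAnalysis(n_components=n_components)
    lda.fit(sig[fit_mask], fit_labels)
    return lda.transform(sig)


def write_classification_tsv(result: MixscapeResult, path) -> None:
    """Write per-cell class and posterior as TSV."""
    result.to_frame().to_csv(path, sep="\t", index=False)
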
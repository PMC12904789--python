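"""Distance metrics between groups of cells, with permutation tests.

Seventeen metrics are registered, covering mean-vector comparisons (MSE,
Euclidean, MAE, cosine, Pearson, R^2, t-statistic, Kendall, Spearman),
distribution comparisons (MMD, energy distance, per-gene Kolmogorov-Smirnov,
Wasserstein / earth mover's, symmetrised Gaussian KL, negative-binomial
log-likelihood) and two classifier-probability metrics. Any metric can be
turned into a Monte-Carlo permutation test of a perturbation against its
control.

Conventions
-----------
* ``X`` is the perturbed group, ``Y`` the control/reference group, both
  cells x features with a shared feature axis.
* Mean-based metrics consume only group summaries (mean/variance/n), so the
  pairwise driver computes each summary once per group.
* MMD and the energy distance default to V-statistic estimators (within-group
  sums include the diagonal, normalised by N^2): these are exactly zero on
  identical groups, and for the linear kernel MMD^2 reduces exactly to
  ||mean(X) - mean(Y)||^2. ``unbiased=True`` switches to the U-statistic
  forms with N(N-1) normalisers.
"""

from __future__ import annotations

import warnings

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.special
import scipy.stats
from scipy.optimize import linear_sum_assignment, linprog
from scipy.spatial.distance import cdist
from sklearn.linear_model import LogisticRegression

from .core import (
    DistanceResult,
    PermutationTestResult,
    as_dense,
    select_representation,
    split_groups,
    summarize_group,
)

__all__ = [
    "MetricSpec",
    "METRICS",
    "metric_ids",
    "distance",
    "pairwise_distances",
    "distance_test",
    "wasserstein_ot",
]

EPS_DEFAULT = 1e-8


@dataclass(frozen=True)
class MetricSpec:
    metric_id: str
    symmetric: bool
    needs_full_matrices: bool
    needs_labels_beyond_pair: bool = False
    zero_diagonal: bool = True
    epsilon: float = EPS_DEFAULT


METRICS = {
    s.metric_id: s
    for s in [
        MetricSpec("mse", True, False),
        MetricSpec("mmd", True, True),
        MetricSpec("euclidean", True, False),
        MetricSpec("edistance", True, True),
        MetricSpec("ks", True, True),
        MetricSpec("mae", True, False),
        MetricSpec("t_stat", True, False),
        MetricSpec("cosine", True, False),
        MetricSpec("pearson", True, False),
        MetricSpec("r2", False, False),
        MetricSpec("classifier_cp", False, True, zero_diagonal=False),
        MetricSpec("kendall", True, False),
        MetricSpec("spearman", True, False),
        MetricSpec("wasserstein", True, True),
        MetricSpec("sym_kl", True, False),
        MetricSpec(
            "classifier_proj", False, True, needs_labels_beyond_pair=True,
            zero_diagonal=False,
        ),
        MetricSpec("nb_ll", False, True, zero_diagonal=False),
    ]
}


def metric_ids() -> list:
    return list(METRICS)


# ---------------------------------------------------------------------------
# mean-vector metrics (operate on GroupSummary pairs)
# ---------------------------------------------------------------------------

def _mse(sx, sy, opts):
    return float(np.mean((sx.mean - sy.mean) ** 2))


def _euclidean(sx, sy, opts):
    return float(np.linalg.norm(sx.mean - sy.mean))


def _mae(sx, sy, opts):
    return float(np.mean(np.abs(sx.mean - sy.mean)))


def _t_stat(sx, sy, opts):
    # Welch-style per-gene t; eps guards zero-variance genes. Reported as
    # the mean of |t| by default so the metric is symmetric; signed=True
    # averages the signed terms instead (antisymmetric).
    eps = opts.get("epsilon", EPS_DEFAULT)
    denom = np.sqrt(sx.variance / sx.n_cells + sy.variance / sy.n_cells + eps)
    t = (sx.mean - sy.mean) / denom
    if opts.get("signed", False):
        return float(np.mean(t))
    return float(np.mean(np.abs(t)))


def _cosine(sx, sy, opts):
    eps = opts.get("epsilon", EPS_DEFAULT)
    x, y = sx.mean, sy.mean
    denom = np.linalg.norm(x) * np.linalg.norm(y)
    if denom < eps:
        return 0.0 if np.allclose(x, y) else 1.0
    val = 1.0 - float(np.dot(x, y) / denom)
    return 0.0 if abs(val) < eps else val


def _pearson(sx, sy, opts):
    x, y = sx.mean, sy.mean
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("pearson distance on a constant mean vector; returning 0")
        return 0.0
    r = float(np.corrcoef(x, y)[0, 1])
    return 1.0 - r


def _r2(sx, sy, opts):
    # Printed form: sum((x-y)^2) / sum((x - mean(x))^2); denominator anchored
    # on the perturbed group, hence the asymmetry.
    eps = opts.get("epsilon", EPS_DEFAULT)
    x, y = sx.mean, sy.mean
    return float(np.sum((x - y) ** 2) / (np.sum((x - x.mean()) ** 2) + eps))


def _kendall(sx, sy, opts):
    # tau-b = (C - D)/sqrt((C+D+X)(C+D+Y)); distance = (1 - tau-b)*n(n-1)/4.
    x, y = sx.mean, sy.mean
    n = len(x)
    tau = scipy.stats.kendalltau(x, y).statistic
    if np.isnan(tau):
        warnings.warn("kendall tau undefined (constant ranking); using tau=0")
        tau = 0.0
    return float((1.0 - tau) * n * (n - 1) / 4.0)


def _spearman(sx, sy, opts):
    # 6*sum(d_i^2)/(n(n^2-1)) on average ranks; equals 1 - rho without ties.
    x, y = sx.mean, sy.mean
    n = len(x)
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    d = rx - ry
    return float(6.0 * np.sum(d**2) / (n * (n**2 - 1)))


def _sym_kl(sx, sy, opts):
    # Per-gene Gaussian KL, symmetrised: 0.5*[KL(X||Y)+KL(Y||X)]; variances
    # floored at eps so zero-variance genes do not blow up.
    eps = opts.get("epsilon", EPS_DEFAULT)
    vx = sx.variance + eps
    vy = sy.variance + eps
    dm2 = (sx.mean - sy.mean) ** 2
    kl_xy = 0.5 * np.log(vy / vx) + (vx + dm2) / (2.0 * vy) - 0.5
    kl_yx = 0.5 * np.log(vx / vy) + (vy + dm2) / (2.0 * vx) - 0.5
    return float(0.5 * (np.sum(kl_xy) + np.sum(kl_yx)))


def sym_kl_discrete(p, q, epsilon: float = EPS_DEFAULT) -> float:
    """Symmetrised discrete KL divergence between two probability vectors."""
    p = np.asarray(p, dtype=float) + epsilon
    q = np.asarray(q, dtype=float) + epsilon
    p = p / p.sum()
    q = q / q.sum()
    kl_pq = float(np.sum(p * np.log(p / q)))
    kl_qp = float(np.sum(q * np.log(q / p)))
    return 0.5 * (kl_pq + kl_qp)


# ---------------------------------------------------------------------------
# full-matrix metrics
# ---------------------------------------------------------------------------

def _mmd(X, Y, opts):
    """Squared MMD with a linear kernel (default; pass kernel='rbf' with a
    gamma for the Gaussian kernel)."""
    kernel = opts.get("kernel", "linear")
    if kernel == "linear":
        Kxx, Kyy, Kxy = X @ X.T, Y @ Y.T, X @ Y.T
    elif kernel == "rbf":
        gamma = opts.get("gamma", 1.0 / X.shape[1])
        Kxx = np.exp(-gamma * cdist(X, X, "sqeuclidean"))
        Kyy = np.exp(-gamma * cdist(Y, Y, "sqeuclidean"))
        Kxy = np.exp(-gamma * cdist(X, Y, "sqeuclidean"))
    else:
        raise ValueError(f"unknown kernel '{kernel}'")
    n, m = X.shape[0], Y.shape[0]
    if opts.get("unbiased", False):
        if n < 2 or m < 2:
            raise ValueError("unbiased MMD needs >= 2 cells per group")
        term_x = (Kxx.sum() - np.trace(Kxx)) / (n * (n - 1))
        term_y = (Kyy.sum() - np.trace(Kyy)) / (m * (m - 1))
    else:
        term_x = Kxx.sum() / (n * n)
        term_y = Kyy.sum() / (m * m)
    return float(term_x + term_y - 2.0 * Kxy.mean())


def _edistance(X, Y, opts):
    """Energy distance 2*d_XY - d_X - d_Y on Euclidean pairwise distances."""
    d_xy = cdist(X, Y).mean()
    Dx, Dy = cdist(X, X), cdist(Y, Y)
    n, m = X.shape[0], Y.shape[0]
    if opts.get("unbiased", False):
        if n < 2 or m < 2:
            raise ValueError("unbiased energy distance needs >= 2 cells per group")
        d_x = Dx.sum() / (n * (n - 1))
        d_y = Dy.sum() / (m * (m - 1))
    else:
        d_x = Dx.mean()
        d_y = Dy.mean()
    return float(2.0 * d_xy - d_x - d_y)


def _ks(X, Y, opts):
    """Mean over genes of the two-sample Kolmogorov-Smirnov statistic."""
    stats = [
        scipy.stats.ks_2samp(X[:, j], Y[:, j], method="asymp").statistic
        for j in range(X.shape[1])
    ]
    return float(np.mean(stats))


def wasserstein_ot(
    X,
    Y,
    exact_limit: int = 2000,
    sinkhorn_reg: float = 0.05,
    sinkhorn_iters: int = 500,
) -> float:
    """First-order Wasserstein distance between two empirical clouds.

    Uniform weights on the rows of X and Y, Euclidean ground cost. Solved
    exactly (assignment problem for equal sizes, transportation LP
    otherwise) when both groups have at most ``exact_limit`` cells;
    otherwise by entropically regularised Sinkhorn iterations (flagged with
    a warning since the result is then an approximation).
    """
    n, m = X.shape[0], Y.shape[0]
    C = cdist(X, Y)
    if max(n, m) <= exact_limit:
        if n == m:
            r, c = linear_sum_assignment(C)
            return float(C[r, c].mean())
        return _ot_lp(C)
    warnings.warn(
        f"groups exceed {exact_limit} cells; using entropic (Sinkhorn) "
        "approximation of the Wasserstein distance"
    )
    return _sinkhorn(C, sinkhorn_reg, sinkhorn_iters)


def _ot_lp(C) -> float:
    # Transportation LP: minimise <T, C> s.t. row sums 1/n, col sums 1/m.
    n, m = C.shape
    a = np.full(n, 1.0 / n)
    b = np.full(m, 1.0 / m)
    A_rows = scipy.sparse.kron(
        scipy.sparse.eye(n), np.ones((1, m)), format="csr"
    )
    A_cols = scipy.sparse.kron(
        np.ones((1, n)), scipy.sparse.eye(m), format="csr"
    )
    A_eq = scipy.sparse.vstack([A_rows, A_cols[:-1]])  # drop one redundant row
    b_eq = np.concatenate([a, b[:-1]])
    res = linprog(
        C.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs"
    )
    if not res.success:  # pragma: no cover - HiGHS handles these sizes
        raise RuntimeError(f"optimal transport LP failed: {res.message}")
    return float(res.fun)


def _sinkhorn(C, reg: float, iters: int) -> float:
    # log-domain Sinkhorn with cost scaled to [0, 1] for stability
    n, m = C.shape
    scale = C.max() if C.max() > 0 else 1.0
    M = C / scale
    log_a = np.full(n, -np.log(n))
    log_b = np.full(m, -np.log(m))
    f = np.zeros(n)  # dual potentials / reg
    g = np.zeros(m)
    K = -M / reg
    for _ in range(iters):
        f = log_a - scipy.special.logsumexp(K + g[None, :], axis=1)
        g = log_b - scipy.special.logsumexp((K + f[:, None]).T, axis=1)
    P = np.exp(K + f[:, None] + g[None, :])
    P /= P.sum()
    return float((P * C).sum())


def _wasserstein(X, Y, opts):
    return wasserstein_ot(
        X,
        Y,
        exact_limit=opts.get("exact_limit", 2000),
        sinkhorn_reg=opts.get("sinkhorn_reg", 0.05),
    )


def _nb_ll(X, Y, opts):
    """Negative mean NB log-likelihood of Y under per-gene fits on X.

    For each overdispersed gene in X (variance > mean), mu and theta are
    estimated by method of moments (theta = mu^2/(var - mu)); genes without
    overdispersion are excluded from the average. Returns the negative
    average log-likelihood, so closer groups score lower.
    """
    eps = opts.get("epsilon", EPS_DEFAULT)
    X = np.asarray(X)
    if not np.allclose(X, np.round(X)) or X.min() < 0:
        raise ValueError("nb_ll requires raw non-negative integer counts in X")
    mu = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros_like(mu)
    keep = var > mu + eps
    if not keep.any():
        raise ValueError(
            "nb_ll: no overdispersed gene in X (variance <= mean everywhere)"
        )
    mu = mu[keep]
    theta = mu**2 / (var[keep] - mu)
    y = np.asarray(Y, dtype=float)[:, keep]
    ll = (
        theta * (np.log(theta + eps) - np.log(theta + mu + eps))
        + y * (np.log(mu + eps) - np.log(theta + mu + eps))
        + scipy.special.gammaln(y + theta)
        - scipy.special.gammaln(theta)
        - scipy.special.gammaln(y + 1.0)
    )
    return float(-ll.mean())


def _classifier_cp(X, Y, opts):
    """Mean control-class probability of held-out perturbed cells.

    A linear softmax classifier (multinomial logistic regression) separates
    control Y from perturbed X, with 20% of X held out; the metric is the
    average predicted probability of the control class on the held-out
    perturbed cells. Near 0.5 for indistinguishable groups, near 0 for
    well-separated ones.
    """
    seed = opts.get("seed")
    if seed is None:
        raise ValueError("classifier_cp requires a seed in opts")
    test_fraction = opts.get("test_fraction", 0.2)
    rng = np.random.default_rng(seed)
    n = X.shape[0]
    n_test = max(1, int(round(test_fraction * n)))
    perm = rng.permutation(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    if len(train_idx) == 0:
        raise ValueError("classifier_cp: perturbed group too small to split")
    Z = np.vstack([X[train_idx], Y])
    labels = np.array([1] * len(train_idx) + [0] * Y.shape[0])
    clf = LogisticRegression(max_iter=opts.get("max_iter", 1000))
    clf.fit(Z, labels)
    proba = clf.predict_proba(X[test_idx])
    control_col = int(np.flatnonzero(clf.classes_ == 0)[0])
    return float(proba[:, control_col].mean())


def _classifier_proj(X, Y, opts):
    """Mean control-class probability of P_i under a classifier trained on
    everything except P_i.

    Requires the full labeled dataset in opts: ``full_data`` (cells x d),
    ``full_labels``, ``group_label`` (the label of X) and ``control_label``.
    """
    for key in ("full_data", "full_labels", "group_label", "control_label"):
        if key not in opts:
            raise ValueError(f"classifier_proj requires '{key}' in opts")
    if opts.get("seed") is None:
        raise ValueError("classifier_proj requires a seed in opts")
    data = as_dense(opts["full_data"])
    labels = np.asarray(opts["full_labels"], dtype=object).astype(str)
    group = str(opts["group_label"])
    control = str(opts["control_label"])
    train_mask = labels != group
    if train_mask.sum() == 0 or (labels == group).sum() == 0:
        raise ValueError("classifier_proj: empty train or target set")
    if np.unique(labels[train_mask]).size < 2:
        raise ValueError(
            "classifier_proj needs at least one non-control group besides "
            f"'{group}' to train a multi-class classifier"
        )
    clf = LogisticRegression(max_iter=opts.get("max_iter", 1000))
    clf.fit(data[train_mask], labels[train_mask])
    if control not in clf.classes_:
        raise ValueError(f"control label '{control}' absent from training classes")
    proba = clf.predict_proba(data[labels == group])
    control_col = int(np.flatnonzero(clf.classes_ == control)[0])
    return float(proba[:, control_col].mean())


_SUMMARY_FUNCS = {
    "mse": _mse,
    "euclidean": _euclidean,
    "mae": _mae,
    "t_stat": _t_stat,
    "cosine": _cosine,
    "pearson": _pearson,
    "r2": _r2,
    "kendall": _kendall,
    "spearman": _spearman,
    "sym_kl": _sym_kl,
}

_MATRIX_FUNCS = {
    "mmd": _mmd,
    "edistance": _edistance,
    "ks": _ks,
    "wasserstein": _wasserstein,
    "nb_ll": _nb_ll,
    "classifier_cp": _classifier_cp,
    "classifier_proj": _classifier_proj,
}


def distance(metric: str, X, Y, **opts) -> float:
    """Distance between perturbed group ``X`` and reference group ``Y``.

    ``X`` and ``Y`` are cells x features matrices (dense or sparse) over the
    same features. Metric-specific options are passed through ``opts``
    (``seed`` for classifier metrics; ``full_data``/``full_labels``/
    ``group_label``/``control_label`` for ``classifier_proj``; ``signed``
    for ``t_stat``; ``unbiased`` for ``mmd``/``edistance``; ``kernel`` for
    ``mmd``).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric '{metric}'; known: {metric_ids()}")
    X = as_dense(X)
    Y = as_dense(Y)
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("group matrices must be 2-d (cells x features)")
    if X.shape[1] != Y.shape[1]:
        raise ValueError(
            f"feature mismatch: X has {X.shape[1]}, Y has {Y.shape[1]}"
        )
    if X.shape[0] == 0 or Y.shape[0] == 0:
        raise ValueError("empty group")
    if metric in _SUMMARY_FUNCS:
        return _SUMMARY_FUNCS[metric](summarize_group(X), summarize_group(Y), opts)
    return _MATRIX_FUNCS[metric](X, Y, opts)


def _distance_from_summaries(metric, sx, sy, opts):
    return _SUMMARY_FUNCS[metric](sx, sy, opts)


def pairwise_distances(
    ds,
    metric: str,
    groupby: str = "perturbation",
    representation: str = "X",
    control_label: str | None = None,
    **opts,
) -> DistanceResult:
    """Group x group distance matrix over a categorical annotation.

    Symmetric metrics are computed once per unordered pair; the diagonal is
    set to 0 for metrics whose self-distance is 0 by definition and computed
    otherwise. Per-pair failures (e.g. a singleton group for a
    variance-based metric) are recorded as NaN with a warning and do not
    abort the run.
    """
    spec = METRICS[metric] if metric in METRICS else None
    if spec is None:
        raise ValueError(f"unknown metric '{metric}'; known: {metric_ids()}")
    groups = split_groups(ds, groupby)
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("pairwise_distances needs at least 2 groups")
    rep = as_dense(select_representation(ds, representation))
    mats = {g: rep[idx] for g, idx in groups.items()}

    if spec.needs_labels_beyond_pair:
        if control_label is None:
            raise ValueError(f"{metric} requires control_label")
        opts = dict(
            opts,
            full_data=rep,
            full_labels=ds.obs[groupby].to_numpy(),
            control_label=control_label,
        )

    summaries = (
        {g: summarize_group(m) for g, m in mats.items()}
        if metric in _SUMMARY_FUNCS
        else None
    )

    k = len(labels)
    values = np.zeros((k, k))
    for i, gi in enumerate(labels):
        for j, gj in enumerate(labels):
            if spec.symmetric and j < i:
                continue
            if i == j and spec.zero_diagonal:
                continue
            pair_opts = dict(opts)
            if spec.needs_labels_beyond_pair:
                pair_opts["group_label"] = gi
            try:
                if summaries is not None:
                    val = _distance_from_summaries(
                        metric, summaries[gi], summaries[gj], pair_opts
                    )
                else:
                    val = _MATRIX_FUNCS[metric](mats[gi], mats[gj], pair_opts)
            except (ValueError, RuntimeError) as exc:
                warnings.warn(f"{metric}({gi}, {gj}) failed: {exc}")
                val = np.nan
            values[i, j] = val
            if spec.symmetric and i != j:
                values[j, i] = val
    return DistanceResult(
        group_labels=labels,
        values=values,
        metric_id=metric,
        symmetric=spec.symmetric,
        representation_used=representation,
    )


def distance_test(
    ds,
    group: str,
    control: str,
    metric: str = "edistance",
    groupby: str = "perturbation",
    representation: str = "X",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    **opts,
) -> PermutationTestResult:
    """Monte-Carlo permutation test of ``group`` against ``control``.

    The null distribution reshuffles the pooled group/control cells into two
    pseudo-groups of the original sizes ``n_perm`` times; the p-value uses
    the add-one estimator p = (1 + #{null >= observed}) / (1 + n_perm), so
    it is never 0 and ties count toward the null.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be >= 19 (p cannot reach 0.05 below that)")
    groups = split_groups(ds, groupby)
    for g in (group, control):
        if g not in groups:
            raise ValueError(f"group '{g}' not found in '{groupby}'")
    rep = as_dense(select_representation(ds, representation))
    Xi, Yi = groups[str(group)], groups[str(control)]
    if "seed" not in opts and METRICS[metric].needs_full_matrices:
        opts = dict(opts, seed=seed)
    observed = distance(metric, rep[Xi], rep[Yi], **opts)

    pool = np.concatenate([Xi, Yi])
    n_x = len(Xi)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(pool)
        null[b] = distance(metric, rep[perm[:n_x]], rep[perm[n_x:]], **opts)
    p = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    return PermutationTestResult(
        metric_id=metric,
        observed=float(observed),
        null_draws=null,
        p_value=float(p),
        alpha=float(alpha),
        significant=bool(p <= alpha),
        n_perm=int(n_perm),
        seed=int(seed),
    )


def distance_matrix_to_csv(result: DistanceResult, path) -> None:
    """Write a labeled group x group distance matrix as CSV."""
    result.to_frame().to_csv(path)
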
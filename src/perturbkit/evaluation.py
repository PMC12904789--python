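"""Metrics for evaluating perturbation-response prediction models.

Two complementary views of how well a predicted perturbed expression matrix
matches the measured one:

* :func:`de_ranking_correlation` asks whether the *differential-expression
  story* is preserved: genes are ranked by a per-gene two-sample t statistic
  (control vs. perturbed), once for the real data and once for the
  prediction, and the Spearman correlation of the two rankings is returned.
* :func:`mean_variance_density_distance` asks whether the predicted
  expression has a realistic mean-variance relationship: per-gene
  (mean, variance) point clouds of real and predicted data are smoothed
  with 2-d Gaussian kernel density estimates and compared on a shared grid.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.stats

from .core import as_dense

__all__ = ["de_ranking_correlation", "mean_variance_density_distance"]


def _t_stats(X, Y) -> np.ndarray:
    """Per-gene Welch t statistics for X vs Y; undefined genes get 0."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t = scipy.stats.ttest_ind(X, Y, axis=0, equal_var=False).statistic
    bad = ~np.isfinite(t)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} gene(s) with undefined t statistic "
            "(constant in both groups); ranked as 0"
        )
        t = np.where(bad, 0.0, t)
    return t


def de_ranking_correlation(control, perturbed, predicted) -> float:
    """Spearman correlation of differential-gene rankings, in [-1, 1].

    Ranks genes by the control-vs-perturbed t statistic and by the
    control-vs-predicted t statistic, then correlates the rankings. 1 means
    the prediction reproduces the differential-expression ordering exactly;
    ~0 means it carries no signal.
    """
    X = as_dense(control)
    Y = as_dense(perturbed)
    Yhat = as_dense(predicted)
    if not (X.shape[1] == Y.shape[1] == Yhat.shape[1]):
        raise ValueError("control, perturbed and predicted must share features")
    t_real = _t_stats(Y, X)
    t_pred = _t_stats(Yhat, X)
    rho = scipy.stats.spearmanr(t_real, t_pred).statistic
    return float(rho)


def mean_variance_density_distance(
    real, predicted, grid_points: int = 100, bw_method=None
) -> float:
    """Mean absolute difference of mean-variance KDE landscapes, >= 0.

    Per-gene (mean, variance) pairs of each matrix are smoothed with a 2-d
    Gaussian KDE (Scott's rule bandwidth by default) and both densities are
    evaluated on a shared ``grid_points`` x ``grid_points`` grid spanning
    the union of the two data ranges. Identical inputs give exactly 0; the
    metric is symmetric in its arguments because the grid is shared.
    """
    Y = as_dense(real)
    Yhat = as_dense(predicted)
    if Y.shape[1] < 2 or Yhat.shape[1] < 2:
        raise ValueError("need at least 2 genes to estimate a 2-d density")
    pts_real = np.vstack([Y.mean(axis=0), Y.var(axis=0)])
    pts_pred = np.vstack([Yhat.mean(axis=0), Yhat.var(axis=0)])

    both = np.hstack([pts_real, pts_pred])
    lo = both.min(axis=1)
    hi = both.max(axis=1)
    pad = 0.05 * np.where(hi > lo, hi - lo, 1.0)
    gx = np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_points)
    gy = np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_points)
    mx, my = np.meshgrid(gx, gy)
    grid = np.vstack([mx.ravel(), my.ravel()])

    dens_real = _kde_eval(pts_real, grid, bw_method)
    dens_pred = _kde_eval(pts_pred, grid, bw_method)
    return float(np.mean(np.abs(dens_real - dens_pred)))


def _kde_eval(points, grid, bw_method) -> np.ndarray:
    # gaussian_kde needs a non-singular covariance; jitter degenerate clouds
    cov = np.cov(points)
    if np.linalg.matrix_rank(np.atleast_2d(cov)) < 2:
        rng = np.random.default_rng(0)
        points = points + rng.normal(scale=1e-9, size=points.shape)
    kde = scipy.stats.gaussian_kde(points, bw_method=bw_method)
    return kde(grid)
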
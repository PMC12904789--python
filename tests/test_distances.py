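"""Metric catalog tests, anchored on independent brute-force oracles."""

import numpy as np
import pytest
import scipy.stats

from perturbkit import METRICS, distance, metric_ids, pairwise_distances
from perturbkit.distances import wasserstein_ot
from tests.conftest import make_gaussian_dataset

ZERO_SELF = [
    m for m, s in METRICS.items() if s.zero_diagonal
]
SYMMETRIC = [m for m, s in METRICS.items() if s.symmetric]


def _pair(rng, n=15, m=12, d=6, shift=0.4):
    X = rng.normal(size=(n, d))
    Y = rng.normal(loc=shift, size=(m, d))
    return X, Y


# ---------------------------------------------------------------------------
# brute-force reference implementations (double loops, no vectorization)
# ---------------------------------------------------------------------------

def brute_edistance(X, Y, unbiased=False):
    def mean_pairwise(A, B, skip_diag_norm):
        total = 0.0
        for a in A:
            for b in B:
                total += np.sqrt(((a - b) ** 2).sum())
        if skip_diag_norm:
            return total / (len(A) * (len(B) - 1))
        return total / (len(A) * len(B))

    d_xy = mean_pairwise(X, Y, False)
    d_x = mean_pairwise(X, X, unbiased)
    d_y = mean_pairwise(Y, Y, unbiased)
    return 2 * d_xy - d_x - d_y


def brute_mmd_linear(X, Y, unbiased=False):
    def k(a, b):
        return float(np.dot(a, b))

    n, m = len(X), len(Y)
    xx = sum(
        k(X[i], X[j]) for i in range(n) for j in range(n)
        if not (unbiased and i == j)
    )
    yy = sum(
        k(Y[i], Y[j]) for i in range(m) for j in range(m)
        if not (unbiased and i == j)
    )
    xy = sum(k(X[i], Y[j]) for i in range(n) for j in range(m))
    nx = n * (n - 1) if unbiased else n * n
    ny = m * (m - 1) if unbiased else m * m
    return xx / nx + yy / ny - 2 * xy / (n * m)


def brute_ks(X, Y):
    stats = []
    for j in range(X.shape[1]):
        x, y = X[:, j], Y[:, j]
        grid = np.concatenate([x, y])
        sup = max(
            abs(np.mean(x <= z) - np.mean(y <= z)) for z in grid
        )
        stats.append(sup)
    return float(np.mean(stats))


def brute_kendall(x, y):
    n = len(x)
    C = D = TX = TY = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                TX += 1
                TY += 1
            elif dx == 0:
                TX += 1
            elif dy == 0:
                TY += 1
            elif dx * dy > 0:
                C += 1
            else:
                D += 1
    tau = (C - D) / np.sqrt((C + D + TX) * (C + D + TY))
    return (1 - tau) * n * (n - 1) / 4


def brute_spearman(x, y):
    n = len(x)
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    return 6 * sum((rx[i] - ry[i]) ** 2 for i in range(n)) / (n * (n**2 - 1))


# ---------------------------------------------------------------------------
# hand-computed and definitional cases
# ---------------------------------------------------------------------------

class TestHandComputedValues:
    def test_mse_single_rows(self):
        assert distance("mse", [[1.0, 2.0]], [[3.0, 4.0]]) == pytest.approx(4.0)

    def test_euclidean_squared_equals_ngenes_times_mse(self, rng):
        for _ in range(20):
            X, Y = _pair(rng, d=7)
            e = distance("euclidean", X, Y)
            m = distance("mse", X, Y)
            assert e**2 == pytest.approx(7 * m, abs=1e-8)

    @pytest.mark.parametrize(
        "metric", ["mse", "euclidean", "edistance", "ks", "mae", "cosine",
                   "wasserstein", "mmd"]
    )
    def test_self_distance_is_zero(self, metric, rng):
        X, _ = _pair(rng)
        assert distance(metric, X, X.copy()) == pytest.approx(0.0, abs=1e-8)

    def test_cosine_collinear_means(self):
        X = np.tile([1.0, 2.0, 3.0], (4, 1))
        Y = 3.0 * X
        assert distance("cosine", X, Y) == pytest.approx(0.0, abs=1e-8)

    def test_mmd_linear_kernel_closed_form(self, rng):
        X = rng.normal(size=(200, 10))
        Y = rng.normal(loc=0.5, size=(200, 10))
        mmd = distance("mmd", X, Y)
        delta = np.linalg.norm(X.mean(0) - Y.mean(0)) ** 2
        assert mmd == pytest.approx(delta, rel=0.15)

    def test_r2_is_asymmetric(self, rng):
        X, Y = _pair(rng, shift=1.0)
        assert distance("r2", X, Y) != pytest.approx(distance("r2", Y, X))


class TestBruteForceOracles:
    @pytest.mark.parametrize("unbiased", [False, True])
    def test_edistance_matches_double_loop(self, rng, unbiased):
        for _ in range(3):
            X, Y = _pair(rng, n=18, m=14, d=8)
            assert distance("edistance", X, Y, unbiased=unbiased) == pytest.approx(
                brute_edistance(X, Y, unbiased), abs=1e-8
            )

    @pytest.mark.parametrize("unbiased", [False, True])
    def test_mmd_matches_double_loop(self, rng, unbiased):
        for _ in range(3):
            X, Y = _pair(rng, n=16, m=12, d=5)
            assert distance("mmd", X, Y, unbiased=unbiased) == pytest.approx(
                brute_mmd_linear(X, Y, unbiased), abs=1e-8
            )

    def test_ks_matches_manual_ecdf(self, rng):
        X, Y = _pair(rng, n=20, m=15, d=6)
        assert distance("ks", X, Y) == pytest.approx(brute_ks(X, Y), abs=1e-8)

    def test_kendall_matches_pair_counting(self, rng):
        X, Y = _pair(rng, d=10)
        assert distance("kendall", X, Y) == pytest.approx(
            brute_kendall(X.mean(0), Y.mean(0)), abs=1e-8
        )

    def test_spearman_matches_rank_formula(self, rng):
        X, Y = _pair(rng, d=10)
        assert distance("spearman", X, Y) == pytest.approx(
            brute_spearman(X.mean(0), Y.mean(0)), abs=1e-8
        )

    def test_wasserstein_1d_matches_scipy(self, rng):
        # independent oracle: scipy's 1-d earth mover's distance
        x = rng.normal(size=(30, 1))
        y = rng.normal(loc=1.0, size=(20, 1))
        assert distance("wasserstein", x, y) == pytest.approx(
            scipy.stats.wasserstein_distance(x.ravel(), y.ravel()), abs=1e-8
        )

    def test_wasserstein_equal_sizes_assignment_matches_lp(self, rng):
        # with equal sizes and uniform weights the transportation LP has an
        # assignment-shaped optimum; the two solvers must agree
        from scipy.spatial.distance import cdist

        from perturbkit.distances import _ot_lp

        X = rng.normal(size=(25, 3))
        Y = rng.normal(loc=0.5, size=(25, 3))
        assert wasserstein_ot(X, Y) == pytest.approx(
            _ot_lp(cdist(X, Y)), abs=1e-8
        )


class TestSymmetryAndGuards:
    @pytest.mark.parametrize("metric", SYMMETRIC)
    def test_declared_symmetric_metrics_are_symmetric(self, metric, rng):
        for _ in range(5):
            X, Y = _pair(rng, shift=rng.normal())
            assert distance(metric, X, Y) == pytest.approx(
                distance(metric, Y, X), abs=1e-8
            )

    def test_asymmetric_set_is_declared(self):
        asym = {m for m, s in METRICS.items() if not s.symmetric}
        assert asym == {"r2", "classifier_cp", "classifier_proj", "nb_ll"}

    def test_seventeen_metrics_registered(self):
        assert len(metric_ids()) == 17

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="feature mismatch"):
            distance("mse", rng.normal(size=(3, 4)), rng.normal(size=(3, 5)))

    def test_unknown_metric_raises(self):
        with pytest.raises(ValueError, match="unknown metric"):
            distance("not_a_metric", np.zeros((2, 2)), np.zeros((2, 2)))

    def test_nb_ll_rejects_non_integer(self, rng):
        with pytest.raises(ValueError, match="integer"):
            distance("nb_ll", rng.normal(size=(20, 3)), rng.normal(size=(20, 3)))

    def test_classifier_requires_seed(self, rng):
        X, Y = _pair(rng)
        with pytest.raises(ValueError, match="seed"):
            distance("classifier_cp", X, Y)


class TestNbLikelihood:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_resample_closer_than_shifted(self, seed):
        rng = np.random.default_rng(seed)
        mu, theta, n = 5.0, 2.0, 500
        p = theta / (theta + mu)
        X = rng.negative_binomial(theta, p, size=(n, 20))
        resample = rng.negative_binomial(theta, p, size=(n, 20))
        shifted = rng.negative_binomial(theta, theta / (theta + 8 * mu), size=(n, 20))
        assert distance("nb_ll", X, resample) < distance("nb_ll", X, shifted)


class TestClassifierMetrics:
    def test_separated_groups_score_near_zero(self, rng):
        X = rng.normal(loc=5.0, size=(60, 5))
        Y = rng.normal(loc=0.0, size=(60, 5))
        assert distance("classifier_cp", X, Y, seed=0) < 0.05

    def test_identical_distributions_score_near_half(self, rng):
        X = rng.normal(size=(200, 5))
        Y = rng.normal(size=(200, 5))
        assert distance("classifier_cp", X, Y, seed=0) == pytest.approx(0.5, abs=0.2)

    def test_classifier_proj_tracks_control_resemblance(self, rng):
        # P_i resembling another perturbation scores a low control
        # probability; P_i resembling the controls scores high
        ctrl = rng.normal(size=(50, 4))
        p_far = rng.normal(loc=-4.0, size=(50, 4))
        p_other = rng.normal(loc=-4.0, size=(50, 4))
        p_ctrl_like = rng.normal(size=(50, 4))
        full = np.vstack([ctrl, p_far, p_other, p_ctrl_like])
        labels = ["c"] * 50 + ["p1"] * 50 + ["p2"] * 50 + ["p3"] * 50
        common = dict(seed=0, full_data=full, full_labels=labels,
                      control_label="c")
        far = distance("classifier_proj", p_far, ctrl,
                       group_label="p1", **common)
        ctrl_like = distance("classifier_proj", p_ctrl_like, ctrl,
                             group_label="p3", **common)
        assert far < 0.1
        assert ctrl_like > 0.5


class TestPairwiseDistances:
    def test_identical_groups_give_zero_matrix(self, rng):
        ds = make_gaussian_dataset(rng, [0.0, 0.0, 0.0], n_cells=20, sd=0.0)
        res = pairwise_distances(ds, "mse")
        np.testing.assert_allclose(res.values, 0.0, atol=1e-12)
        assert res.symmetric

    def test_symmetric_result_matches_transpose(self, rng):
        ds = make_gaussian_dataset(rng, [0.0, 0.5, 1.0], n_cells=25)
        res = pairwise_distances(ds, "edistance")
        np.testing.assert_allclose(res.values, res.values.T, atol=1e-8)

    def test_asymmetric_metric_flagged_and_differs(self, rng):
        ds = make_gaussian_dataset(rng, [0.0, 1.0, 2.0], n_cells=25)
        res = pairwise_distances(ds, "r2")
        assert not res.symmetric
        off = res.values[np.triu_indices(3, 1)]
        assert not np.allclose(res.values, res.values.T)
        assert np.all(off >= 0)

    def test_known_mean_shifts_recovered(self, rng):
        n_genes = 30
        shifts = [0.0, 1.0, 2.0, 3.0]
        ds = make_gaussian_dataset(rng, shifts, n_cells=400, n_genes=n_genes)
        res = pairwise_distances(ds, "mse")
        df = res.to_frame()
        for i, si in enumerate(shifts):
            for j, sj in enumerate(shifts):
                if i == j:
                    continue
                expected = (si - sj) ** 2  # per-gene squared mean shift
                assert df.iloc[i, j] == pytest.approx(expected, rel=0.10, abs=0.02)

    def test_single_group_rejected(self, rng):
        ds = make_gaussian_dataset(rng, [0.0], n_cells=10)
        with pytest.raises(ValueError, match="2 groups"):
            pairwise_distances(ds, "mse")
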
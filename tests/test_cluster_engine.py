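import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans

from monnet import (cluster_profiles, did, did_curve, kmeans_best, suggest_k)
from monnet.cluster_engine import DidCurve


def brute_force_did(assignment, Y):
    """Longhand double-loop evaluation of the DiD formula."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    J = Y.shape[1]
    acc = 0.0
    for j in range(J):
        col = Y[:, j]
        sse = sum((v - col.mean()) ** 2 for v in col)
        ssw = 0.0
        for k in np.unique(assignment):
            members = col[np.asarray(assignment) == k]
            ssw += sum((v - members.mean()) ** 2 for v in members)
        acc += ssw / sse
    return 100.0 * (1.0 - acc / J)


class TestKmeansBest:
    def test_single_cluster_ssw_equals_sse(self, blobs3):
        X, _ = blobs3
        sol = kmeans_best(X, K=1, n_restarts=3, seed=0)
        sse = ((X - X.mean(axis=0)) ** 2).sum()
        assert sol.total_ssw == pytest.approx(sse)
        assert (sol.assignment == 0).all()

    def test_two_separated_blobs_recovered(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.5, (30, 2)),
                       rng.normal(20, 0.5, (30, 2))])
        sol = kmeans_best(X, K=2, n_restarts=10, seed=1)
        labels = sol.assignment
        assert len(set(labels[:30])) == 1 and len(set(labels[30:])) == 1
        assert labels[0] != labels[30]
        within = sum(((X[s] - X[s].mean(axis=0)) ** 2).sum()
                     for s in (slice(0, 30), slice(30, 60)))
        assert sol.total_ssw == pytest.approx(within)

    def test_lloyd_iterations_never_increase_ssw(self, blobs3):
        X, _ = blobs3
        for K in (2, 3, 5):
            sol = kmeans_best(X, K=K, n_restarts=5, seed=3, keep_history=True)
            h = sol.ssw_history
            assert all(b <= a + 1e-9 for a, b in zip(h, h[1:]))

    def test_seed_reproducibility(self, blobs3):
        X, _ = blobs3
        a = kmeans_best(X, K=4, n_restarts=20, seed=11)
        b = kmeans_best(X, K=4, n_restarts=20, seed=11)
        assert np.array_equal(a.assignment, b.assignment)
        assert a.total_ssw == b.total_ssw
        assert a.restart_index == b.restart_index

    def test_matches_sklearn_on_separated_data(self, blobs3):
        # independent implementation finds the same optimum
        X, _ = blobs3
        ours = kmeans_best(X, K=3, n_restarts=20, seed=5)
        ref = KMeans(n_clusters=3, n_init=20, random_state=0).fit(X)
        assert ours.total_ssw == pytest.approx(ref.inertia_, rel=1e-9)

    def test_ssw_matrix_sums_to_total(self, blobs3):
        X, _ = blobs3
        sol = kmeans_best(X, K=3, n_restarts=5, seed=7)
        assert sol.ssw_per_cluster_per_characteristic.shape == (3, 2)
        assert sol.ssw_per_cluster_per_characteristic.sum() == pytest.approx(
            sol.total_ssw)

    def test_k_out_of_range_rejected(self):
        X = np.zeros((5, 2))  # one distinct row
        with pytest.raises(ValueError, match="distinct"):
            kmeans_best(X, K=2, n_restarts=1, seed=0)
        with pytest.raises(ValueError, match="empty"):
            kmeans_best(np.empty((0, 2)), K=1, n_restarts=1, seed=0)


class TestDid:
    def test_one_cluster_is_zero(self):
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(40, 3))
        assert did(np.zeros(40, dtype=int), Y) == pytest.approx(0.0)

    def test_singleton_clusters_give_hundred(self):
        rng = np.random.default_rng(1)
        Y = rng.normal(size=(25, 2))
        assert did(np.arange(25), Y) == pytest.approx(100.0)

    def test_six_point_hand_case(self):
        # two characteristics, two clusters of three points
        Y = np.array([[0.0, 10.0], [1.0, 12.0], [2.0, 14.0],
                      [10.0, 0.0], [11.0, 1.0], [12.0, 2.0]])
        assignment = np.array([0, 0, 0, 1, 1, 1])
        # characteristic 1: SSW = 2 + 2 = 4, grand mean 6, SSE = 154
        # characteristic 2: SSW = 8 + 2 = 10, grand mean 6.5, SSE = 191.5
        expected = 100 * (1 - 0.5 * (4 / 154 + 10 / 191.5))
        assert did(assignment, Y) == pytest.approx(expected)
        assert did(assignment, Y) == pytest.approx(brute_force_did(assignment, Y))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 101))
        J = int(rng.integers(1, 6))
        K = int(rng.integers(1, min(n, 8)))
        Y = rng.normal(size=(n, J))
        assignment = rng.integers(0, K, n)
        assert did(assignment, Y) == pytest.approx(
            brute_force_did(assignment, Y), abs=1e-9)

    def test_constant_characteristic_rejected(self):
        Y = np.column_stack([np.arange(10.0), np.ones(10)])
        with pytest.raises(ValueError, match="constant"):
            did(np.zeros(10, dtype=int), Y)


class TestDidCurve:
    def test_three_blob_curves_plateau_at_three(self, blobs3):
        X, labels = blobs3
        preds = X @ np.array([1.0, 0.5])  # a linear "prediction" feature
        curve = did_curve(X, preds, k_max=6, n_restarts=10, seed=0)
        assert curve.did_covariates[0] == pytest.approx(0.0)
        assert curve.did_predictions[0] == pytest.approx(0.0)
        assert (curve.did_covariates >= 0).all()
        assert (curve.did_covariates <= 100).all()
        assert (curve.did_predictions <= 100).all()
        assert curve.did_covariates[2] > 99  # k=3 separates the blobs
        assert curve.did_covariates[5] - curve.did_covariates[2] < 1

    def test_suggest_k_on_blobs(self, blobs3):
        X, _ = blobs3
        preds = X @ np.array([1.0, 0.5])
        curve = did_curve(X, preds, k_max=6, n_restarts=10, seed=0)
        assert suggest_k(curve, marginal_gain_threshold=1.0) == 3


class TestSuggestK:
    @staticmethod
    def linear_curve(kmax, step):
        ks = np.arange(1, kmax + 1)
        vals = np.minimum(step * (ks - 1), 100.0)
        return DidCurve(k_values=ks, did_predictions=vals,
                        did_covariates=vals)

    def test_steadily_rising_curve_falls_back_to_k_max(self):
        curve = self.linear_curve(10, 5.0)
        with pytest.warns(UserWarning, match="plateau"):
            assert suggest_k(curve, marginal_gain_threshold=2.0) == 10

    def test_minimum_suggestion_is_two(self):
        curve = self.linear_curve(10, 0.001)
        assert suggest_k(curve, marginal_gain_threshold=100.0) == 2


class TestClusterProfiles:
    def test_single_cluster_profile_is_column_means(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 4))
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        prof = cluster_profiles(np.zeros(30, dtype=int), Xs)
        np.testing.assert_allclose(prof.to_numpy()[0], np.zeros(4),
                                   atol=1e-12)

    def test_known_cluster_means_recovered(self):
        X = np.array([[1.0, 10.0], [3.0, 12.0], [5.0, 20.0], [7.0, 30.0]])
        prof = cluster_profiles(np.array([0, 0, 1, 1]), X)
        np.testing.assert_allclose(prof.to_numpy(),
                                   [[2.0, 11.0], [6.0, 25.0]])

    def test_size_weighted_profile_average_is_zero_on_scaled_data(self, blobs3):
        X, labels = blobs3
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        prof = cluster_profiles(labels, Xs)
        sizes = np.bincount(labels)
        weighted = (prof.to_numpy() * sizes[:, None]).sum(axis=0) / sizes.sum()
        np.testing.assert_allclose(weighted, np.zeros(2), atol=1e-12)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            cluster_profiles(np.array([0, 0, 2]), np.zeros((3, 1)))
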
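import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from mdscape.cluster import (
    ClusterModel,
    assign,
    cluster_weights,
    fit_gmm,
    match_labels,
    populations_by_condition,
    representative_frames,
    responsibilities,
    scan_k,
    silhouette,
)


def _silhouette_oracle(x, labels):
    """Textbook a(i)/b(i) double loop."""
    scores = np.zeros(len(x))
    for i in range(len(x)):
        same = [j for j in range(len(x)) if labels[j] == labels[i] and j != i]
        if not same:
            continue  # singleton: score 0
        a = np.mean([np.linalg.norm(x[i] - x[j]) for j in same])
        b = min(
            np.mean([np.linalg.norm(x[i] - x[j]) for j in range(len(x)) if labels[j] == other])
            for other in set(labels) - {labels[i]}
        )
        scores[i] = (b - a) / max(a, b)
    return scores


class TestFitGMM:
    def test_single_component_closed_form(self, rng):
        x = rng.normal(size=(100, 3)) * [1.0, 2.0, 0.5]
        model = fit_gmm(x, K=1)
        np.testing.assert_allclose(model.weights, [1.0])
        np.testing.assert_allclose(model.means[0], x.mean(axis=0), atol=1e-12)
        np.testing.assert_allclose(
            model.covariances[0],
            np.cov(x.T, ddof=0) + 1e-6 * np.eye(3),
            atol=1e-10,
        )

    def test_separated_blobs_recovered_exactly(self, blob_scores):
        x, truth = blob_scores
        model = fit_gmm(x, K=2, seed=0)
        labels = assign(model, x)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_agrees_with_sklearn_mixture(self, blob_scores):
        # independent route: sklearn's EM on the same data finds the same basins
        x, truth = blob_scores
        ours = fit_gmm(x, K=2, seed=0)
        ref = GaussianMixture(2, covariance_type="full", random_state=0).fit(x)
        order_ours = np.argsort(ours.means[:, 0])
        order_ref = np.argsort(ref.means_[:, 0])
        np.testing.assert_allclose(
            ours.means[order_ours], ref.means_[order_ref], atol=0.05
        )
        np.testing.assert_allclose(
            np.sort(ours.weights), np.sort(ref.weights_), atol=0.01
        )

    def test_loglik_path_monotone(self, rng):
        x = np.vstack([rng.normal(size=(150, 2)), rng.normal(size=(150, 2)) + 4])
        for k in (2, 3, 4):
            model = fit_gmm(x, K=k, seed=1, n_init=3)
            assert np.all(np.diff(model.ll_path) >= -1e-8)

    def test_k_exceeding_frames_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_gmm(rng.normal(size=(5, 2)), K=6)

    def test_degenerate_identical_data_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_gmm(np.zeros((50, 2)), K=2)


class TestScanK:
    def test_single_k_range(self, blob_scores):
        x, _ = blob_scores
        report = scan_k(x, k_min=2, k_max=2, seed=0, n_init=2)
        assert len(report.table) == 1
        assert report.elbow_k is None
        assert report.best_silhouette_k == 2

    def test_two_far_basins_best_silhouette_at_two(self, blob_scores):
        x, _ = blob_scores
        report = scan_k(x, k_min=2, k_max=5, seed=0, n_init=3)
        assert report.best_silhouette_k == 2

    def test_empty_range_rejected(self, blob_scores):
        x, _ = blob_scores
        with pytest.raises(ValueError):
            scan_k(x, k_min=4, k_max=3)

    def test_elbow_recovers_planted_k(self, rng):
        # four well-separated planted basins in 2-D
        centers = np.array([[0, 0], [15, 0], [0, 15], [15, 15]], dtype=float)
        x = np.vstack([rng.normal(size=(120, 2)) + c for c in centers])
        report = scan_k(x, k_min=2, k_max=7, seed=0, n_init=5)
        assert report.elbow_k == 4


class TestSilhouette:
    def test_matches_brute_force_on_two_pairs(self):
        x = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        labels = np.array([0, 0, 1, 1])
        mean, scores = silhouette(x, labels)
        oracle = _silhouette_oracle(x, labels)
        np.testing.assert_allclose(scores, oracle, atol=1e-12)
        assert mean == pytest.approx(oracle.mean())

    def test_far_separation_approaches_one(self, rng):
        x = np.vstack([rng.normal(size=(50, 2)), rng.normal(size=(50, 2)) + 300])
        mean, _ = silhouette(x, np.repeat([0, 1], 50))
        assert mean >= 0.99

    def test_all_singletons_score_zero(self):
        x = np.arange(6, dtype=float).reshape(-1, 1)
        mean, scores = silhouette(x, np.arange(6))
        assert mean == 0.0
        np.testing.assert_array_equal(scores, 0.0)

    def test_single_cluster_rejected(self, rng):
        with pytest.raises(ValueError):
            silhouette(rng.normal(size=(10, 2)), np.zeros(10, dtype=int))

    def test_scores_bounded(self, rng):
        x = rng.normal(size=(200, 3))
        labels = rng.integers(0, 4, size=200)
        _, scores = silhouette(x, labels)
        assert np.all(scores >= -1) and np.all(scores <= 1)

    def test_subsampling_is_seeded(self, rng):
        x = rng.normal(size=(400, 2))
        x[200:] += 8
        labels = np.repeat([0, 1], 200)
        a, _ = silhouette(x, labels, max_n=100, seed=5)
        b, _ = silhouette(x, labels, max_n=100, seed=5)
        assert a == b


class TestAssignment:
    @pytest.fixture
    def symmetric_model(self):
        return ClusterModel(
            weights=np.array([0.5, 0.5]),
            means=np.array([[-1.0], [1.0]]),
            covariances=np.array([[[1.0]], [[1.0]]]),
            log_likelihood=0.0,
            seed=0,
        )

    def test_point_at_mean_assigned_there(self, symmetric_model):
        assert assign(symmetric_model, np.array([[1.0]]))[0] == 1

    def test_equidistant_tie_takes_lower_index(self, symmetric_model):
        assert assign(symmetric_model, np.array([[0.0]]))[0] == 0

    def test_responsibilities_normalized(self, symmetric_model, rng):
        resp = responsibilities(symmetric_model, rng.normal(size=(50, 1)))
        np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-10)

    def test_dimension_mismatch(self, symmetric_model, rng):
        with pytest.raises(ValueError):
            assign(symmetric_model, rng.normal(size=(5, 3)))


class TestSummaries:
    def test_cluster_weights_examples(self):
        np.testing.assert_allclose(cluster_weights([0, 0, 1, 1]), [0.5, 0.5])
        np.testing.assert_allclose(cluster_weights([0, 0, 0]), [1.0])

    def test_weights_empty_rejected(self):
        with pytest.raises(ValueError):
            cluster_weights([])

    def test_single_condition_equals_weights(self):
        labels = np.array([0, 1, 1, 2])
        meta = pd.DataFrame({"condition": ["apo"] * 4})
        table = populations_by_condition(labels, meta)
        np.testing.assert_allclose(table.loc["apo"].to_numpy(), cluster_weights(labels))

    def test_rows_normalized_per_condition(self, rng):
        labels = rng.integers(0, 3, size=60)
        meta = pd.DataFrame({"condition": ["apo"] * 30 + ["RNA"] * 30})
        table = populations_by_condition(labels, meta)
        np.testing.assert_allclose(table.sum(axis=1), 1.0, atol=1e-10)

    def test_missing_condition_rejected(self):
        meta = pd.DataFrame({"condition": ["apo", ""]})
        with pytest.raises(ValueError):
            populations_by_condition(np.array([0, 1]), meta)


class TestRepresentatives:
    def test_exact_mean_match(self):
        model = ClusterModel(
            weights=np.array([1.0]),
            means=np.array([[2.0, 2.0]]),
            covariances=np.eye(2)[None],
            log_likelihood=0.0,
            seed=0,
        )
        x = np.array([[0.0, 0.0], [2.0, 2.0], [5.0, 5.0]])
        reps = representative_frames(model, x, np.zeros(3, dtype=int))
        assert reps == {0: 1}

    def test_tie_takes_lower_frame_index(self):
        model = ClusterModel(
            weights=np.array([1.0]),
            means=np.array([[1.0]]),
            covariances=np.eye(1)[None],
            log_likelihood=0.0,
            seed=0,
        )
        reps = representative_frames(model, np.array([[0.0], [2.0]]), np.zeros(2, dtype=int))
        assert reps == {0: 0}

    def test_empty_cluster_rejected(self):
        model = ClusterModel(
            weights=np.array([0.5, 0.5]),
            means=np.array([[0.0], [5.0]]),
            covariances=np.repeat(np.eye(1)[None], 2, axis=0),
            log_likelihood=0.0,
            seed=0,
        )
        with pytest.raises(ValueError, match="no assigned frames"):
            representative_frames(model, np.array([[0.0], [0.1]]), np.zeros(2, dtype=int))


class TestLabelPermutationInvariance:
    def test_weights_ari_silhouette_invariant(self, blob_scores, rng):
        x, truth = blob_scores
        labels = assign(fit_gmm(x, K=2, seed=0), x)
        permuted = 1 - labels
        assert sorted(cluster_weights(labels)) == sorted(cluster_weights(permuted))
        assert adjusted_rand_score(truth, labels) == adjusted_rand_score(truth, permuted)
        assert silhouette(x, labels)[0] == pytest.approx(silhouette(x, permuted)[0])

    def test_match_labels_aligns_permutation(self, rng):
        truth = rng.integers(0, 3, size=100)
        permuted = (truth + 1) % 3
        np.testing.assert_array_equal(match_labels(permuted, truth), truth)
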
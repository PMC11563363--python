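"""Distances, silhouettes, the refinement loop, initializations, PAM and
the uniform method contract."""

import numpy as np
import pytest
from sklearn.datasets import make_blobs
from sklearn.metrics import adjusted_rand_score, silhouette_samples

from cdrsubtypes import (
    SillyPuttyConfig,
    hierarchical_init,
    mean_silhouette,
    pairwise_distances,
    pam,
    random_init,
    run_method,
    silhouette_widths,
    sillyputty_refine,
)
from conftest import best_pam_cost, naive_silhouette, pam_cost

LINE4 = np.array([[0.0], [1.0], [10.0], [11.0]])


class TestPairwiseDistances:
    def test_identical_rows_distance_zero(self):
        d = pairwise_distances(np.array([[1.0, 2.0], [1.0, 2.0]]))
        assert d.values[0, 1] == 0.0

    def test_three_four_five_triangle(self):
        d = pairwise_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_agrees_with_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.random((10, 4))
        d = pairwise_distances(x).values
        for i in range(10):
            for j in range(10):
                assert d[i, j] == pytest.approx(
                    np.sqrt(((x[i] - x[j]) ** 2).sum()), abs=1e-12
                )

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            pairwise_distances(np.eye(3), metric="nonsense")


class TestSilhouetteWidths:
    def test_two_pair_line_example(self):
        d = pairwise_distances(LINE4)
        s = silhouette_widths(d, np.array([1, 1, 2, 2]))
        assert s[0] == pytest.approx((10.5 - 1) / 10.5)   # ~0.9048
        assert s[1] == pytest.approx((9.5 - 1) / 9.5)     # ~0.8947
        assert mean_silhouette(s) == pytest.approx(0.89975, abs=1e-5)

    def test_singleton_scores_zero(self):
        d = pairwise_distances(np.array([[0.0], [5.0], [6.0]]))
        s = silhouette_widths(d, np.array([1, 2, 2]))
        assert s[0] == 0.0

    def test_coincident_clusters_score_one(self):
        x = np.array([[0.0], [0.0], [9.0], [9.0]])
        s = silhouette_widths(pairwise_distances(x), np.array([1, 1, 2, 2]))
        np.testing.assert_allclose(s, 1.0)

    def test_single_cluster_rejected(self):
        d = pairwise_distances(LINE4)
        with pytest.raises(ValueError):
            silhouette_widths(d, np.array([1, 1, 1, 1]))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_naive_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 50))
        k = int(rng.integers(2, 5))
        x = rng.random((n, 3))
        labels = rng.integers(1, k + 1, n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 1, 2
        d = pairwise_distances(x)
        np.testing.assert_allclose(
            silhouette_widths(d, labels), naive_silhouette(d.values, labels), atol=1e-12
        )

    def test_matches_sklearn_without_singletons(self):
        rng = np.random.default_rng(5)
        x = rng.random((40, 3))
        labels = np.repeat([1, 2, 3, 4], 10)
        d = pairwise_distances(x)
        np.testing.assert_allclose(
            silhouette_widths(d, labels),
            silhouette_samples(d.values, labels, metric="precomputed"),
            atol=1e-10,
        )


class TestMeanSilhouette:
    def test_all_ones(self):
        assert mean_silhouette(np.ones(5)) == 1.0

    def test_all_singletons_scores_zero(self):
        d = pairwise_distances(LINE4)
        s = silhouette_widths(d, np.arange(4))
        assert mean_silhouette(s) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_silhouette([])


class TestSillyPuttyRefine:
    def test_clean_start_terminates_immediately(self):
        x, y = make_blobs(n_samples=60, centers=3, cluster_std=0.3, random_state=0)
        sol = sillyputty_refine(pairwise_distances(x), y + 1)
        assert sol.n_iterations == 0
        assert sol.termination == "no_negative_at_start"
        np.testing.assert_array_equal(sol.labels, y + 1)

    def test_recovers_pairs_from_alternating_start(self):
        d = pairwise_distances(LINE4)
        sol = sillyputty_refine(d, np.array([1, 2, 1, 2]))
        assert len(set(sol.labels[:2].tolist())) == 1
        assert len(set(sol.labels[2:].tolist())) == 1
        assert sol.labels[0] != sol.labels[2]
        assert sol.msw == pytest.approx(0.89975, abs=1e-5)
        assert sol.termination == "all_nonnegative"

    def test_iteration_cap_contract(self):
        with pytest.raises(ValueError):
            SillyPuttyConfig(max_iterations=0)
        d = pairwise_distances(LINE4)
        sol = sillyputty_refine(
            d, np.array([1, 2, 1, 2]), SillyPuttyConfig(max_iterations=1)
        )
        assert sol.n_iterations == 1
        if sol.silhouette.min() < 0:
            assert sol.termination == "max_iterations"

    def test_single_initial_cluster_rejected(self):
        d = pairwise_distances(LINE4)
        with pytest.raises(ValueError):
            sillyputty_refine(d, np.ones(4, dtype=int))

    @pytest.mark.parametrize("seed", range(10))
    def test_returned_silhouettes_consistent_with_labels(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.random((40, 3))
        d = pairwise_distances(x)
        sol = sillyputty_refine(d, random_init(40, 4, seed))
        assert sol.n_iterations <= SillyPuttyConfig().max_iterations
        np.testing.assert_allclose(
            sol.silhouette, silhouette_widths(d, sol.labels), atol=1e-9
        )
        assert sol.msw == pytest.approx(mean_silhouette(sol.silhouette))

    def test_nonnegative_when_claimed(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.random((30, 2))
            sol = sillyputty_refine(pairwise_distances(x), random_init(30, 3, seed))
            if sol.termination == "all_nonnegative":
                hits += 1
                assert sol.silhouette.min() >= 0
        assert hits > 0


class TestInitializations:
    def test_hierarchical_k_equals_n_gives_singletons(self):
        d = pairwise_distances(LINE4)
        labels = hierarchical_init(d, 4)
        assert len(np.unique(labels)) == 4

    @pytest.mark.parametrize("linkage", ["ward", "complete", "average", "single"])
    def test_hierarchical_separates_line_pairs(self, linkage):
        d = pairwise_distances(LINE4)
        labels = hierarchical_init(d, 2, linkage)
        assert labels[0] == labels[1] != labels[2] == labels[3]

    def test_hierarchical_k_one_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_init(pairwise_distances(LINE4), 1)

    def test_random_init_seed_determinism(self):
        np.testing.assert_array_equal(random_init(30, 4, 9), random_init(30, 4, 9))

    def test_random_init_full_occupancy_at_k_equals_n(self):
        labels = random_init(4, 4, 0)
        assert sorted(labels.tolist()) == [1, 2, 3, 4]

    def test_random_init_uniform_occupancy(self):
        rng_counts = np.zeros(4)
        for seed in range(2000):
            labels = random_init(100, 4, seed)
            for c in range(1, 5):
                rng_counts[c - 1] += (labels == c).sum()
        frac = rng_counts / rng_counts.sum()
        np.testing.assert_allclose(frac, 0.25, atol=0.01)

    def test_random_init_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            random_init(3, 4, 0)


class TestPam:
    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_optimum_on_tiny_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        x = rng.random((n, 2))
        d = pairwise_distances(x).values
        labels = pam(d, 2)
        medoids = [
            int(np.flatnonzero(labels == c)[np.argmin(d[labels == c][:, labels == c].sum(axis=1))])
            for c in np.unique(labels)
        ]
        # recompute the medoid set cost from the assignment's own medoids
        assert pam_cost(d, medoids) == pytest.approx(best_pam_cost(d, 2), abs=1e-9)

    def test_separated_blobs_recovered(self):
        x, y = make_blobs(n_samples=90, centers=3, cluster_std=0.3, random_state=1)
        labels = pam(pairwise_distances(x).values, 3)
        assert adjusted_rand_score(y, labels) == 1.0


@pytest.fixture(scope="module")
def blobs():
    x, y = make_blobs(n_samples=90, centers=3, cluster_std=0.25, random_state=2)
    # squash into [0,1]^2 like preprocessed features
    x = (x - x.min(0)) / (x.max(0) - x.min(0))
    return x, y


class TestRunMethod:

    @pytest.mark.parametrize(
        "method",
        ["hierarchical_sillyputty", "random_sillyputty", "hierarchical", "pam", "kmeans"],
    )
    def test_separated_blobs_fully_recovered(self, blobs, method):
        x, y = blobs
        cfg = SillyPuttyConfig(random_restarts=20)
        sol = run_method(x, method, k=3, seed=4, config=cfg)
        assert adjusted_rand_score(y, sol.labels) == 1.0

    def test_dbscan_recovers_tight_blobs(self, blobs):
        x, y = blobs
        sol = run_method(x, "dbscan", dbscan_eps=0.1, dbscan_min_samples=5)
        assert sol.method["n_core_clusters"] == 3
        assert adjusted_rand_score(y, sol.labels) > 0.95

    def test_dbscan_single_cluster_flagged_invalid(self):
        rng = np.random.default_rng(0)
        x = rng.random((40, 2)) * 0.05  # one dense clump
        sol = run_method(x, "dbscan", dbscan_eps=0.25)
        assert sol.method["valid_for_msw"] is False

    def test_hierarchical_sillyputty_is_refined_hierarchical(self, blobs):
        x, _ = blobs
        d = pairwise_distances(x)
        direct = sillyputty_refine(d, hierarchical_init(d, 3))
        composed = run_method(x, "hierarchical_sillyputty", k=3)
        np.testing.assert_array_equal(direct.labels, composed.labels)
        assert composed.msw == pytest.approx(direct.msw)

    @pytest.mark.parametrize("method", ["hierarchical_sillyputty", "random_sillyputty", "kmeans", "pam"])
    def test_same_seed_reproduces_solution(self, blobs, method):
        x, _ = blobs
        cfg = SillyPuttyConfig(random_restarts=5)
        a = run_method(x, method, k=3, seed=11, config=cfg)
        b = run_method(x, method, k=3, seed=11, config=cfg)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.msw == b.msw

    def test_unknown_method_and_missing_k_rejected(self, blobs):
        x, _ = blobs
        with pytest.raises(ValueError, match="unknown method"):
            run_method(x, "spectral", k=3)
        with pytest.raises(ValueError, match="requires k"):
            run_method(x, "kmeans")
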
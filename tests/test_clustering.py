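from itertools import product

import numpy as np
import pytest
from sklearn.cluster import KMeans

import hospgroups as hg
from hospgroups.clustering import _centers, _sse
from hospgroups.data_model import InputError


def plain_features(X):
    """Wrap a raw coordinate array as a feature matrix (no CI block)."""
    X = np.asarray(X, dtype=float)
    return hg.FeatureMatrix(
        facilities=[f"F{i}" for i in range(X.shape[0])],
        units=[],
        distance_columns=[f"c{j}" for j in range(X.shape[1])],
        values=X,
        d_max=1.0,
    )


def brute_force_min_sse(X, K):
    """Exhaustive minimum of J(C) over all K-group assignments."""
    n = X.shape[0]
    best = np.inf
    for assign in product(range(K), repeat=n):
        labels = np.array(assign)
        if len(set(assign)) < K:
            continue
        centers = _centers(X, labels, K)
        best = min(best, _sse(X, labels, centers))
    return best


class TestWardPartition:
    def test_recovers_separated_clouds(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (5, 2)), rng.normal(10, 0.1, (5, 2))])
        sol = hg.ward_partition(plain_features(X), 2)
        assert len(set(sol.labels[:5])) == 1 and len(set(sol.labels[5:])) == 1
        assert sol.labels[0] != sol.labels[5]

    def test_singletons_at_k_equals_n(self):
        X = np.arange(8.0).reshape(4, 2)
        sol = hg.ward_partition(plain_features(X), 4)
        assert sol.rss == 0.0 and sol.r2 == 1.0

    def test_matches_exhaustive_minimum_when_separated(self):
        rng = np.random.default_rng(1)
        X = np.vstack([rng.normal(0, 0.2, (3, 2)), rng.normal(5, 0.2, (3, 2))])
        sol = hg.ward_partition(plain_features(X), 2)
        assert sol.rss == pytest.approx(brute_force_min_sse(X, 2), rel=1e-9)

    def test_k_out_of_range(self):
        with pytest.raises(InputError, match="out of range"):
            hg.ward_partition(plain_features(np.eye(3)), 5)


class TestKMeansRefine:
    def test_fixed_point_at_local_optimum(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        fm = plain_features(X)
        seed = np.array([[0.0, 0.5], [10.0, 0.5]])
        sol = hg.kmeans_refine(fm, seed)
        np.testing.assert_allclose(sol.centers, seed)

    def test_descent_from_any_seed(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 3))
        fm = plain_features(X)
        for trial in range(5):
            seed_pts = X[rng.choice(12, size=3, replace=False)]
            # SSE of the seed partition (nearest-seed assignment, seed centers)
            from scipy.spatial.distance import cdist
            labels = cdist(X, seed_pts).argmin(axis=1)
            seed_sse = float(((X - seed_pts[labels]) ** 2).sum())
            sol = hg.kmeans_refine(fm, seed_pts)
            assert sol.rss <= seed_sse + 1e-9

    def test_matches_exhaustive_minimum_small(self):
        """n=8, K=3: Lloyd from Ward seeds finds the global SSE optimum."""
        rng = np.random.default_rng(5)
        X = np.vstack([
            rng.normal([0, 0], 0.3, (3, 2)),
            rng.normal([6, 0], 0.3, (3, 2)),
            rng.normal([3, 5], 0.3, (2, 2)),
        ])
        fm = plain_features(X)
        sol = hg.ward_kmeans(fm, 3)
        best = brute_force_min_sse(X, 3)
        assert sol.rss == pytest.approx(best, rel=1e-9)

    def test_refined_never_below_exhaustive(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(7, 2))
        fm = plain_features(X)
        for K in (2, 3):
            sol = hg.ward_kmeans(fm, K)
            assert sol.rss >= brute_force_min_sse(X, K) - 1e-9

    def test_agrees_with_sklearn_from_same_seed(self):
        """Independent cross-check: sklearn Lloyd from identical seeds."""
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 4))
        fm = plain_features(X)
        seed = hg.ward_partition(fm, 4).centers
        ours = hg.kmeans_refine(fm, seed)
        ref = KMeans(n_clusters=4, init=seed, n_init=1, algorithm="lloyd",
                     tol=1e-12, max_iter=1000).fit(X)
        assert ours.rss == pytest.approx(ref.inertia_, rel=1e-6)

    def test_empty_cluster_repaired(self):
        # both seed centers nearest to the same side forces an empty group
        X = np.array([[0.0], [0.1], [0.2], [10.0]])
        fm = plain_features(X)
        seed = np.array([[0.1], [100.0]])
        sol = hg.kmeans_refine(fm, seed)
        assert sol.K == 2
        assert len(set(sol.labels)) == 2


class TestSweepAndStats:
    def test_sweep_counts(self):
        rng = np.random.default_rng(4)
        fm = plain_features(rng.normal(size=(10, 2)))
        sols = hg.sweep(fm)
        assert [s.K for s in sols] == [1] + list(range(2, 10))

    def test_r2_nondecreasing_and_bounds(self, strong_features):
        sols = hg.sweep(strong_features)
        r2 = [s.r2 for s in sols]
        assert r2[0] == 0.0
        assert all(b >= a - 1e-9 for a, b in zip(r2, r2[1:]))

    def test_k_n_minus_1_has_one_doubleton(self):
        rng = np.random.default_rng(6)
        fm = plain_features(rng.normal(size=(6, 2)))
        sol = hg.ward_kmeans(fm, 5)
        sizes = sorted(np.bincount(sol.labels))
        assert sizes == [1, 1, 1, 1, 2]

    def test_fit_stats_hand_oracle(self):
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        fm = plain_features(X)
        rss, tss, r2 = hg.fit_stats(fm, np.array([0, 0, 1, 1]))
        assert rss == pytest.approx(4.0)      # 1+1+1+1 about means 1 and 11
        assert tss == pytest.approx(104.0)    # about grand mean 6
        assert r2 == pytest.approx(1 - 4 / 104)

    def test_fit_stats_external_mapping(self):
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        fm = plain_features(X)
        rss, _, _ = hg.fit_stats(fm, {"F0": "a", "F1": "a", "F2": "b", "F3": "b"})
        assert rss == pytest.approx(4.0)

    def test_fit_stats_one_group_r2_zero(self, strong_features):
        _, _, r2 = hg.fit_stats(strong_features, np.zeros(strong_features.n, dtype=int))
        assert r2 == pytest.approx(0.0, abs=1e-12)

    def test_fit_stats_singletons_r2_one(self, strong_features):
        _, _, r2 = hg.fit_stats(strong_features, np.arange(strong_features.n))
        assert r2 == pytest.approx(1.0)

    def test_fit_stats_unknown_facility(self, strong_features):
        with pytest.raises(InputError, match="unknown"):
            hg.fit_stats(strong_features, {"nope": 1})


class TestDeterminismAndSeeding:
    def test_sweep_is_deterministic(self, strong_features):
        a = hg.sweep(strong_features)
        b = hg.sweep(strong_features)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.labels, sb.labels)
            assert sa.rss == sb.rss

    def test_random_start_experiment_reproducible(self, strong_features):
        r1, s1 = hg.random_start_experiment(strong_features, 4, runs=5, seed=42)
        r2, s2 = hg.random_start_experiment(strong_features, 4, runs=5, seed=42)
        assert r1 == r2 and s1 == s2

    def test_all_runs_zero_rss_at_k_equals_n(self):
        rng = np.random.default_rng(8)
        fm = plain_features(rng.normal(size=(5, 2)))
        rss, seeded = hg.random_start_experiment(fm, 5, runs=3, seed=0)
        assert max(rss) == pytest.approx(0.0, abs=1e-12)
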
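import numpy as np
import pytest
from scipy.spatial.distance import cdist

from protospec.prototypes import (ClusterConfig, PrototypeSet, adp_select,
                                  cluster_features, identify_prototypes,
                                  kmeans_lloyd, label_prototypes,
                                  select_medoids)


def two_blobs(rng, n=30, sep=20.0, dim=5, spread=1.0):
    a = rng.normal(0.0, spread, (n, dim))
    b = rng.normal(0.0, spread, (n, dim)) + sep
    return np.vstack([a, b]), np.array([0] * n + [1] * n)


class TestKmeans:
    def test_separated_blobs_recovered(self, rng):
        X, truth = two_blobs(rng)
        _, assign, _ = kmeans_lloyd(X, 2, seed=0)
        same = (assign == truth).mean()
        assert same in (0.0, 1.0)  # equal up to label permutation

    def test_k1_centroid_is_column_mean(self, rng):
        X = rng.normal(size=(40, 3))
        centroids, _, _ = kmeans_lloyd(X, 1, seed=0)
        np.testing.assert_allclose(centroids[0], X.mean(axis=0))

    def test_k_equals_n_zero_inertia(self, rng):
        X = rng.normal(size=(8, 3))
        centroids, assign, traj = kmeans_lloyd(X, 8, seed=0)
        assert traj[-1] < 1e-12
        assert sorted(assign.tolist()) == list(range(8))

    def test_k_exceeding_n_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_lloyd(rng.normal(size=(3, 2)), 5)

    def test_identical_rows_degenerate(self):
        with pytest.raises(ValueError, match="identical"):
            kmeans_lloyd(np.ones((10, 3)), 2)

    def test_inertia_trajectory_non_increasing(self, rng):
        X = rng.normal(size=(100, 4))
        _, _, traj = kmeans_lloyd(X, 5, seed=1)
        assert all(b <= a + 1e-9 for a, b in zip(traj, traj[1:]))

    def test_matches_sklearn_objective(self, rng):
        """Independent cross-check: our Lloyd restarts reach (essentially)
        the same within-cluster sum of squares as sklearn's k-means."""
        from sklearn.cluster import KMeans
        X, _ = two_blobs(rng, n=50)
        _, _, traj = kmeans_lloyd(X, 2, seed=0)
        ref = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X).inertia_
        assert traj[-1] <= ref * 1.001 + 1e-9


class TestAdp:
    def test_identical_rows_single_prototype(self):
        protos = adp_select(np.ones((12, 4)))
        assert protos.shape == (1, 4)

    def test_single_row_is_its_own_peak_with_unit_density(self, rng):
        x = rng.normal(size=(1, 6))
        protos = adp_select(x)
        np.testing.assert_array_equal(protos, x)
        # density of the sample mean is 1 by construction
        mu = x.mean(axis=0)
        assert 1.0 / (1.0 + np.sum((x[0] - mu) ** 2) / 1.0) == 1.0

    def test_two_far_blobs_two_prototypes(self, rng):
        X, truth = two_blobs(rng, n=25, sep=50.0, spread=0.5)
        protos = adp_select(X, radius_factor=1.0)
        assert len(protos) == 2
        owners = cdist(protos, X).argmin(axis=1)
        assert {truth[o] for o in owners} == {0, 1}

    def test_permutation_invariant_prototype_set(self, rng):
        X, _ = two_blobs(rng, n=20, sep=30.0)
        perm = rng.permutation(len(X))
        a = adp_select(X, 1.0)
        b = adp_select(X[perm], 1.0)
        assert {tuple(np.round(r, 9)) for r in a} == {tuple(np.round(r, 9)) for r in b}

    def test_prototypes_are_data_rows(self, rng):
        X = rng.normal(size=(50, 3))
        protos = adp_select(X, 0.5)
        for p in protos:
            assert (np.abs(X - p).sum(axis=1) == 0).any()


class TestMedoids:
    def test_exact_match_selected(self, rng):
        X = rng.normal(size=(20, 4))
        idx = select_medoids(X, X[[7]])
        assert idx.tolist() == [7]

    def test_matches_exhaustive_minimum(self, rng):
        X = rng.normal(size=(200, 6))
        C = rng.normal(size=(5, 6))
        idx = select_medoids(X, C)
        brute = []
        for c in C:
            d = [np.sum((x - c) ** 2) for x in X]
            j = int(np.argmin(d))
            if j not in brute:
                brute.append(j)
        assert idx.tolist() == brute

    def test_tie_goes_to_lower_index(self):
        X = np.array([[1.0], [3.0], [1.0]])
        idx = select_medoids(X, np.array([[2.0]]))
        assert idx.tolist() == [0]

    def test_duplicate_winners_collapsed(self, rng):
        X = rng.normal(size=(10, 2))
        idx = select_medoids(X, np.vstack([X[3], X[3] + 1e-9]))
        assert idx.tolist() == [3]


class TestIdentifyPrototypes:
    def test_labeled_kmeans_count_per_class(self, rng):
        X, truth = two_blobs(rng, n=30)
        labels = ["a" if t == 0 else "b" for t in truth]
        ps = identify_prototypes(X, labels, ClusterConfig(method="kmeans", k=3))
        assert len(ps) == 6
        assert sorted(ps.labels) == ["a"] * 3 + ["b"] * 3

    def test_medoid_property(self, rng):
        X, truth = two_blobs(rng, n=15)
        labels = ["a" if t == 0 else "b" for t in truth]
        ps = identify_prototypes(X, labels, ClusterConfig(method="adp"))
        for i, f in zip(ps.indices, ps.features):
            np.testing.assert_array_equal(X[i], f)

    def test_plugin_clustering_hook(self, rng):
        X, _ = two_blobs(rng, n=10)
        cfg = ClusterConfig(method="plugin",
                            plugin=lambda F: F[[0, 10]])  # one row per blob
        ps = identify_prototypes(X, None, cfg)
        assert ps.indices.tolist() == [0, 10]

    def test_meanshift_on_separated_blobs(self, rng):
        X, _ = two_blobs(rng, n=25, sep=50.0, spread=0.5)
        ps = identify_prototypes(X, None, ClusterConfig(method="meanshift"))
        assert len(ps) >= 2

    def test_unlabeled_then_labeled_by_majority(self, rng):
        X, truth = two_blobs(rng, n=20, sep=40.0)
        ps = identify_prototypes(X, None, ClusterConfig(method="kmeans", k=2))
        assert ps.labels is None
        with pytest.raises(ValueError, match="unlabeled"):
            _ = ps.classes
        few = np.concatenate([np.arange(5), np.arange(20, 25)])
        labeled = label_prototypes(ps, X[few],
                                   ["a" if truth[i] == 0 else "b" for i in few])
        assert sorted(labeled.labels) == ["a", "b"]

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            identify_prototypes(np.empty((0, 4)), None)

    def test_degenerate_class_capped_to_single_prototype(self, rng):
        # one class's rows all identical (a collapsed feature map): k-means k
        # is capped at the distinct-row count instead of erroring
        X = np.vstack([np.tile([1.0, 2.0, 3.0], (10, 1)),
                       rng.normal(5, 1, (10, 3))])
        labels = ["flat"] * 10 + ["ok"] * 10
        ps = identify_prototypes(X, labels, ClusterConfig(method="kmeans", k=3))
        assert ps.labels.count("flat") == 1
        assert ps.labels.count("ok") == 3


def test_prototype_set_round_trip(tmp_path, rng):
    X = rng.normal(size=(10, 4))
    ps = PrototypeSet(np.array([1, 4]), X[[1, 4]], ["a", "b"], {"method": "test"})
    ps.save(tmp_path / "protos")
    back = PrototypeSet.load(tmp_path / "protos")
    assert back.indices.tolist() == [1, 4]
    assert back.labels == ["a", "b"]
    np.testing.assert_allclose(back.features, ps.features, rtol=1e-9)
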
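import numpy as np
import pytest
from scipy.spatial.distance import cdist

from protospec.classify import (IdealModel, ideal_predict, pca_lda_fit,
                                pca_lda_predict, xdnn_fit, xdnn_predict)
from protospec.prototypes import ClusterConfig, PrototypeSet, identify_prototypes


def labeled_blobs(rng, n=25, sep=15.0, dim=8):
    X = np.vstack([rng.normal(0, 1, (n, dim)), rng.normal(sep, 1, (n, dim))])
    y = ["alpha"] * n + ["beta"] * n
    return X, y


def make_ideal(rng, n=25, k=3):
    X, y = labeled_blobs(rng, n)
    ps = identify_prototypes(X, y, ClusterConfig(method="kmeans", k=k))
    return X, y, IdealModel(ps)


class TestIdeal:
    def test_query_at_prototype_has_zero_distance(self, rng):
        X, y, model = make_ideal(rng)
        p0 = model.prototypes.features[0]
        pred = ideal_predict(p0, model)
        assert pred.labels[0] == model.prototypes.labels[0]
        assert pred.distances[0, 0] == 0.0

    def test_equals_brute_force_nearest_prototype(self, rng):
        """Oracle: plain 1-NN over the prototype features."""
        from sklearn.neighbors import KNeighborsClassifier
        X, y, model = make_ideal(rng)
        Q = rng.normal(5.0, 6.0, (100, X.shape[1]))
        knn = KNeighborsClassifier(n_neighbors=1).fit(
            model.prototypes.features, model.prototypes.labels)
        np.testing.assert_array_equal(ideal_predict(Q, model).labels,
                                      knn.predict(Q))

    def test_all_training_samples_as_prototypes_is_1nn(self, rng):
        from sklearn.neighbors import KNeighborsClassifier
        X, y = labeled_blobs(rng, n=25, sep=3.0)
        ps = PrototypeSet(np.arange(len(X)), X, list(y))
        model = IdealModel(ps)
        Q = rng.normal(1.5, 3.0, (60, X.shape[1]))
        knn = KNeighborsClassifier(n_neighbors=1).fit(X, y)
        np.testing.assert_array_equal(ideal_predict(Q, model).labels,
                                      knn.predict(Q))

    def test_dimension_mismatch_rejected(self, rng):
        _, _, model = make_ideal(rng)
        with pytest.raises(ValueError, match="dimension"):
            ideal_predict(np.ones((2, 3)), model)

    def test_needs_two_classes(self, rng):
        X = rng.normal(size=(5, 3))
        ps = PrototypeSet(np.arange(5), X, ["only"] * 5)
        with pytest.raises(ValueError, match="2 classes"):
            IdealModel(ps)

    def test_similarity_transform_bounded(self, rng):
        X, y = labeled_blobs(rng, sep=1.5)
        X = X * 0.2  # keep squared distances small enough that exp(-d^2) > 0
        ps = identify_prototypes(X, y, ClusterConfig(method="kmeans", k=2))
        model = IdealModel(ps, similarity="exp_neg_sq_dist")
        pred = ideal_predict(rng.normal(0.2, 0.3, (20, X.shape[1])), model)
        assert np.all(pred.similarities > 0) and np.all(pred.similarities <= 1)


class TestXdnn:
    def test_density_is_one_at_class_mean(self, rng):
        X, y = labeled_blobs(rng)
        model = xdnn_fit(X, y)
        for c, cls in enumerate(model.class_vocab):
            assert np.isclose(model.density(model.class_means[c], cls)[0], 1.0)

    def test_density_half_at_one_scatter(self, rng):
        X, y = labeled_blobs(rng)
        model = xdnn_fit(X, y)
        c = 0
        mu = model.class_means[c]
        direction = np.zeros_like(mu)
        direction[0] = np.sqrt(model.class_scatter[c])
        assert np.isclose(model.density(mu + direction, model.class_vocab[c])[0], 0.5)

    def test_density_strictly_decreasing_in_distance(self, rng):
        X, y = labeled_blobs(rng)
        model = xdnn_fit(X, y)
        mu = model.class_means[0]
        radii = np.linspace(0, 10, 8)
        step = np.zeros_like(mu)
        step[1] = 1.0
        vals = [model.density(mu + r * step, model.class_vocab[0])[0] for r in radii]
        assert all(b < a for a, b in zip(vals, vals[1:]))

    def test_typicality_sums_to_one_per_class(self, rng):
        X, y = labeled_blobs(rng)
        model = xdnn_fit(X, y)
        for cls in model.class_vocab:
            assert abs(model.typicality[cls].sum() - 1.0) < 1e-12

    def test_query_at_prototype_confident(self, rng):
        X, y = labeled_blobs(rng)
        model = xdnn_fit(X, y)
        cls = model.class_vocab[1]
        p = model.prototypes[cls][0]
        labels, conf, firing = xdnn_predict(p, model)
        assert labels[0] == cls
        assert np.isclose(conf[0, 1], 1.0)
        assert firing[0] == model.rules[cls]

    def test_matches_brute_force_confidences(self, rng):
        X, y = labeled_blobs(rng, sep=4.0)
        model = xdnn_fit(X, y)
        Q = rng.normal(2.0, 3.0, (100, X.shape[1]))
        labels, conf, _ = xdnn_predict(Q, model)
        for qi in range(len(Q)):
            lam = {}
            for c, cls in enumerate(model.class_vocab):
                sims = [np.exp(-np.sum((Q[qi] - p) ** 2) / model.class_scatter[c])
                        for p in model.prototypes[cls]]
                lam[cls] = max(sims)
            assert labels[qi] == max(model.class_vocab, key=lambda c: lam[c])
            np.testing.assert_allclose(conf[qi],
                                       [lam[c] for c in model.class_vocab])

    def test_separable_classes_perfect(self, rng):
        Xtr, ytr = labeled_blobs(rng, sep=25.0)
        model = xdnn_fit(Xtr, ytr)
        Xte, yte = labeled_blobs(np.random.default_rng(99), sep=25.0)
        labels, _, _ = xdnn_predict(Xte, model)
        assert labels == yte

    def test_singleton_class_flagged(self, rng):
        X = np.vstack([rng.normal(0, 1, (10, 4)), rng.normal(9, 1, (1, 4))])
        y = ["a"] * 10 + ["b"]
        model = xdnn_fit(X, y)
        assert any("global mean scatter" in f for f in model.flags)
        assert len(model.prototypes["b"]) == 1

    def test_rules_reference_prototypes(self, rng):
        X, y = labeled_blobs(rng)
        model = xdnn_fit(X, y)
        for cls, rule in model.rules.items():
            assert rule.startswith("IF ") and f"THEN {cls!r}" in rule


class TestPcaLda:
    def test_two_classes_one_discriminant_axis(self, rng):
        X, y = labeled_blobs(rng)
        model = pca_lda_fit(X, y, 5)
        assert model.transform(X).shape == (len(X), 1)

    def test_separable_training_data_perfect(self, rng):
        X, y = labeled_blobs(rng, sep=10.0)
        model = pca_lda_fit(X, y, 6)
        assert pca_lda_predict(X, model) == y

    def test_full_rank_projection_preserves_distances(self, rng):
        from protospec.preprocess import standardize_features
        X = rng.normal(size=(20, 10))
        y = ["a"] * 10 + ["b"] * 10
        model = pca_lda_fit(X, y, 10)
        Z, *_ = standardize_features(X)
        T = model.pca.transform(Z)
        np.testing.assert_allclose(cdist(T, T), cdist(Z, Z), atol=1e-8)

    def test_components_beyond_rank_rejected(self, rng):
        X, y = labeled_blobs(rng, n=4, dim=50)  # 8 samples -> rank <= 7
        with pytest.raises(ValueError, match="achievable rank"):
            pca_lda_fit(X, y, 20)

    def test_component_bounds_enforced(self, rng):
        X, y = labeled_blobs(rng)
        with pytest.raises(ValueError, match=r"\[1, 100\]"):
            pca_lda_fit(X, y, 0)

    def test_unstandardized_input_warns(self, rng):
        X, y = labeled_blobs(rng, sep=30.0)
        with pytest.warns(UserWarning, match="standardized"):
            pca_lda_fit(X + 100.0, y, 3, standardize=False)

    def test_duplicate_rows_identical_labels(self, rng):
        X, y = labeled_blobs(rng)
        model = pca_lda_fit(X, y, 4)
        q = rng.normal(7, 5, (1, X.shape[1]))
        pred = pca_lda_predict(np.vstack([q, q]), model)
        assert pred[0] == pred[1]

    def test_accuracy_sweep_saturates(self, rng):
        """Accuracy vs number of components on separable data: rises, then
        stays flat within 2% per step once separation is captured."""
        X, y = labeled_blobs(rng, n=40, sep=8.0, dim=20)
        Xte, yte = labeled_blobs(np.random.default_rng(5), n=40, sep=8.0, dim=20)
        accs = []
        for nc in (1, 2, 5, 10, 15, 19):
            model = pca_lda_fit(X, y, nc)
            accs.append(np.mean(np.asarray(pca_lda_predict(Xte, model)) == yte))
        assert accs[-1] > 0.95
        assert all(b >= a - 0.02 for a, b in zip(accs, accs[1:]))
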
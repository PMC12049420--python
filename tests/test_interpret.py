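import numpy as np
import pytest

from protospec.classify import IdealModel, ideal_predict
from protospec.interpret import (explain_query, named_bands, partition_bands,
                                 radar_table, voronoi_projection)
from protospec.prototypes import PrototypeSet


@pytest.fixture()
def grid():
    return np.linspace(600.0, 1640.0, 950)


def gaussian(grid, center, amp=1.0, fwhm=40.0):
    sd = fwhm / (2 * np.sqrt(2 * np.log(2)))
    return amp * np.exp(-0.5 * ((grid - center) / sd) ** 2)


class TestRadarTable:
    def test_identical_prototype_all_zero(self, grid, rng):
        q = rng.random(950)
        table = radar_table(q, {"same": q.copy()}, grid)
        assert np.all(table["same"].to_numpy() == 0.0)

    def test_partition_sum_of_squares_identity(self, grid, rng):
        q, p = rng.random(950), rng.random(950)
        table = radar_table(q, {"p": p}, grid, bands=partition_bands(grid, 16))
        assert abs((table["p"] ** 2).sum() - np.sum((q - p) ** 2)) < 1e-10

    def test_per_point_mode(self, grid, rng):
        q, p = rng.random(950), rng.random(950)
        table = radar_table(q, {"p": p}, grid, bands="per-point")
        np.testing.assert_allclose(table["p"].to_numpy(), np.abs(q - p))

    def test_band_outside_grid_rejected(self, grid, rng):
        with pytest.raises(ValueError, match="outside"):
            radar_table(rng.random(950), {"p": rng.random(950)}, grid,
                        bands=[(500.0, 700.0)])

    def test_reversal_localized_to_960_band(self, grid):
        """p1 closer everywhere except around the 960 band, where p2 is closer."""
        bands = partition_bands(grid, 16)
        lo_960, hi_960 = next(b for b in bands if b[0] <= 960 < b[1])
        q = gaussian(grid, 1200.0)
        p1 = q + 0.05                       # uniformly offset: close everywhere
        p2 = q + 0.20                       # farther everywhere ...
        window = (grid >= lo_960) & (grid < hi_960)
        p2 = np.where(window, q, p2)        # ... except at the 960 band
        table = radar_table(q, {"p1": p1, "p2": p2}, grid, bands=bands)
        gap = table["p1"].to_numpy() - table["p2"].to_numpy()  # >0 where p2 closer
        reversal_bands = {table.index[i] for i in np.flatnonzero(gap > 0)}
        in_960 = {table.index[i] for i, (lo, hi) in enumerate(bands)
                  if lo <= 960 < hi}
        assert reversal_bands == in_960

    def test_named_bands_cover_known_positions(self):
        bands = named_bands()
        assert bands["phosphate_960"] == (945.0, 975.0)
        assert set(bands) == {"phosphate_960", "carbonate_1070",
                              "amide_III_1240", "amide_III_1270", "CH2_1450"}


class TestExplainQuery:
    def make_model(self, grid, rng, n_classes=2):
        centers = [900.0, 1000.0, 1200.0, 1400.0][:n_classes]
        X, labels = [], []
        for ci, c in enumerate(centers):
            for _ in range(5):
                X.append(gaussian(grid, c) + rng.normal(0, 0.01, grid.size))
                labels.append(f"class{ci}")
        X = np.asarray(X)
        ps = PrototypeSet(np.arange(0, len(X), 5), X[::5],
                          [labels[i] for i in range(0, len(X), 5)])
        return X, labels, IdealModel(ps)

    def test_query_equal_to_prototype_source(self, grid, rng):
        X, labels, model = self.make_model(grid, rng)
        qi = model.prototypes.indices[0]
        exp = explain_query(X[qi], X[qi], model, X, grid, query_id="q0")
        cls = model.prototypes.labels[0]
        assert exp.per_class[cls]["prototype_index"] == qi
        assert exp.per_class[cls]["spectral_distance"] == 0.0
        assert exp.winner == cls

    def test_winner_matches_classifier(self, grid, rng):
        X, labels, model = self.make_model(grid, rng)
        q = X[7]
        exp = explain_query(q, q, model, X, grid)
        assert exp.winner == ideal_predict(q, model).labels[0]

    def test_four_class_model_lists_four_prototypes(self, grid, rng):
        X, labels, model = self.make_model(grid, rng, n_classes=4)
        exp = explain_query(X[3], X[3], model, X, grid)
        assert len(exp.per_class) == 4
        assert set(exp.per_class) == set(model.class_vocab)

    def test_divergent_spaces_noted(self, grid, rng):
        # feature space disagrees with spectral space: swap feature vectors
        X, labels, model = self.make_model(grid, rng)
        q_spec = X[0]          # spectrally a class0 sample
        q_feat = X[5]          # feature-identical to the class1 prototype
        exp = explain_query(q_spec, q_feat, model, X, grid)
        assert exp.winner == "class1"
        assert "feature space" in exp.note

    def test_json_serializable(self, grid, rng):
        import json
        X, labels, model = self.make_model(grid, rng)
        exp = explain_query(X[2], X[2], model, X, grid)
        payload = json.loads(exp.to_json())
        assert payload["winner"] == exp.winner


class TestVoronoi:
    def test_projection_is_two_dimensional(self, rng):
        F = rng.normal(size=(50, 16))
        vm = voronoi_projection(F[:5], F)
        assert vm.prototype_coords.shape == (5, 2)
        assert vm.sample_coords.shape == (50, 2)

    def test_assignment_is_nearest_projected_prototype(self, rng):
        from scipy.spatial.distance import cdist
        F = rng.normal(size=(40, 10))
        vm = voronoi_projection(F[:4], F)
        brute = cdist(vm.sample_coords, vm.prototype_coords).argmin(axis=1)
        np.testing.assert_array_equal(vm.assignment_2d, brute)

    def test_square_corners_single_central_vertex(self, rng):
        # 2-D features: PCA is a rigid map, the tessellation vertex of a
        # square's corners is its center, equidistant from all four
        P = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        samples = np.vstack([P, rng.random((30, 2))])
        vm = voronoi_projection(P, samples)
        assert vm.voronoi is not None
        assert len(vm.voronoi.vertices) == 1
        d = np.linalg.norm(vm.prototype_coords - vm.voronoi.vertices[0], axis=1)
        np.testing.assert_allclose(d, d[0], atol=1e-9)

    def test_too_few_prototypes_notice(self, rng):
        F = rng.normal(size=(20, 6))
        vm = voronoi_projection(F[:2], F)
        assert vm.voronoi is None
        assert "2 prototypes" in vm.notice

    def test_disagreement_rate_reported(self, rng):
        F = rng.normal(size=(60, 20))
        vm = voronoi_projection(F[:6], F)
        assert 0.0 <= vm.disagreement_rate <= 1.0


def test_plot_helpers_render(tmp_path, grid, rng):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from protospec.interpret import plot_radar, plot_voronoi

    table = radar_table(rng.random(950), {"a": rng.random(950),
                                          "b": rng.random(950)}, grid)
    ax = plot_radar(table, title="demo")
    ax.figure.savefig(tmp_path / "radar.png")
    F = rng.normal(size=(40, 12))
    ax2 = plot_voronoi(voronoi_projection(F[:5], F))
    ax2.figure.savefig(tmp_path / "voronoi.png")
    plt.close("all")
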
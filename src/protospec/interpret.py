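"""Explanation artifacts for prototype-based decisions.

Three views of "why this label":

* :func:`explain_query` — the nearest prototype of every class, with both the
  feature-space and the raw-spectral-space l2 distance; the winner always
  equals the classifier's own decision (the explanation is the decision rule,
  not a post-hoc story).
* :func:`radar_table` — per-wavenumber-band distances between a query and
  each nearest prototype, origin-at-query convention (the query is the center
  of the radar plot; a curve closer to the origin is more similar). Bands
  partition the preprocessed grid, so the band-wise squared distances sum
  exactly to the full squared spectral distance.
* :func:`voronoi_projection` — a 2-D PCA map of all samples with the Voronoi
  tessellation of the projected prototypes. The 2-D cell assignment is a
  visualization; whenever it disagrees with the full-dimensional nearest
  prototype, the disagreement rate is reported rather than hidden.

Classification runs in encoder feature space while the radar view compares
raw preprocessed spectra; when the two spaces would name different winners,
the explanation carries an explicit note instead of overriding the decision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .classify import IdealModel, ideal_predict

__all__ = [
    "Explanation",
    "explain_query",
    "radar_table",
    "partition_bands",
    "named_bands",
    "voronoi_projection",
    "VoronoiMap",
    "plot_radar",
    "plot_voronoi",
]

# dentine band positions (cm^-1) used for the named radar bands
NAMED_BAND_CENTERS = {
    "phosphate_960": 960.0,
    "carbonate_1070": 1070.0,
    "amide_III_1240": 1240.0,
    "amide_III_1270": 1270.0,
    "CH2_1450": 1450.0,
}


def partition_bands(grid: np.ndarray, n_bands: int = 16) -> list[tuple[float, float]]:
    """n equal-width contiguous bands covering [grid[0], grid[-1]]."""
    edges = np.linspace(grid[0], grid[-1], n_bands + 1)
    return [(float(edges[i]), float(edges[i + 1])) for i in range(n_bands)]


def named_bands(half_width: float = 15.0) -> dict[str, tuple[float, float]]:
    """The canonical dentine bands as (center - hw, center + hw) intervals."""
    return {name: (c - half_width, c + half_width)
            for name, c in NAMED_BAND_CENTERS.items()}


def _band_members(grid: np.ndarray, bands: list[tuple[float, float]]) -> list[np.ndarray]:
    """Grid indices per band; contiguous partition bands own their left edge,
    the last band additionally owns the right edge."""
    members = []
    for i, (lo, hi) in enumerate(bands):
        if lo < grid[0] - 1e-9 or hi > grid[-1] + 1e-9:
            raise ValueError(f"band [{lo}, {hi}] lies outside the grid "
                             f"[{grid[0]}, {grid[-1]}]")
        if i == len(bands) - 1:
            mask = (grid >= lo) & (grid <= hi)
        else:
            mask = (grid >= lo) & (grid < hi)
        members.append(np.flatnonzero(mask))
    return members


def radar_table(query: np.ndarray, prototypes: dict[str, np.ndarray] | np.ndarray,
                grid: np.ndarray, bands="default") -> pd.DataFrame:
    """Per-band distances between the query and each prototype spectrum.

    ``bands`` may be ``"default"`` (16 equal-width bands over the grid),
    ``"per-point"`` (one row per grid point, |q_w - p_w|), or an explicit list
    of (lo, hi) intervals. For a partition of the grid the squared band
    distances sum to the full squared l2 distance.
    """
    grid = np.asarray(grid, dtype=float)
    q = np.asarray(query, dtype=float)
    if isinstance(prototypes, dict):
        names = list(prototypes)
        P = np.stack([np.asarray(prototypes[n], dtype=float) for n in names])
    else:
        P = np.atleast_2d(np.asarray(prototypes, dtype=float))
        names = [f"prototype_{i}" for i in range(len(P))]
    if P.shape[1] != len(grid) or len(q) != len(grid):
        raise ValueError("query/prototypes must lie on the given grid")
    diff = np.abs(P - q)  # origin-at-query: distance 0 means "at the center"
    if isinstance(bands, str) and bands == "per-point":
        return pd.DataFrame(diff.T, index=pd.Index(grid, name="wavenumber_cm1"),
                            columns=names)
    if isinstance(bands, str) and bands == "default":
        bands = partition_bands(grid)
    members = _band_members(grid, list(bands))
    rows = [np.sqrt((diff[:, m] ** 2).sum(axis=1)) if len(m) else np.zeros(len(P))
            for m in members]
    index = pd.Index([f"{lo:.0f}-{hi:.0f}" for lo, hi in bands], name="band_cm1")
    return pd.DataFrame(np.stack(rows), index=index, columns=names)


@dataclass
class Explanation:
    """Everything needed to render the nearest-prototype story for one query."""

    query_id: str
    winner: str
    per_class: dict[str, dict]          # class -> prototype idx + both distances
    radar: pd.DataFrame = field(repr=False)
    note: str = ""

    def to_json(self) -> str:
        payload = {"query_id": self.query_id, "winner": self.winner,
                   "per_class": self.per_class, "note": self.note,
                   "radar": {c: self.radar[c].tolist() for c in self.radar.columns},
                   "radar_bands": list(self.radar.index)}
        return json.dumps(payload, indent=2)


def explain_query(query_spectrum: np.ndarray, query_feature: np.ndarray,
                  model: IdealModel, train_spectra: np.ndarray,
                  grid: np.ndarray, bands="default",
                  query_id: str = "query") -> Explanation:
    """Build the full explanation record for one preprocessed query.

    ``train_spectra`` are the preprocessed spectra the prototype indices point
    into (so raw prototype spectra can be attached). For every class the
    nearest prototype under feature-space l2 is reported with its feature and
    spectral distances; the winner is the global feature-space argmin and by
    construction equals :func:`protospec.classify.ideal_predict`.
    """
    pred = ideal_predict(query_feature, model)
    protos = model.prototypes
    q = np.asarray(query_spectrum, dtype=float)
    per_class: dict[str, dict] = {}
    nearest_spectra: dict[str, np.ndarray] = {}
    for cls in model.class_vocab:
        cls_pos = np.flatnonzero([l == cls for l in protos.labels])
        if len(cls_pos) == 0:
            raise ValueError(f"class {cls!r} has no prototype")
        dists = pred.distances[0, cls_pos]
        best = cls_pos[dists.argmin()]
        src = train_spectra[protos.indices[best]]
        per_class[cls] = {
            "prototype_index": int(protos.indices[best]),
            "feature_distance": float(dists.min()),
            "spectral_distance": float(np.linalg.norm(q - src)),
        }
        nearest_spectra[cls] = src
    winner = pred.labels[0]
    spectral_winner = min(per_class, key=lambda c: per_class[c]["spectral_distance"])
    note = ""
    if spectral_winner != winner:
        note = (f"feature-space winner {winner!r} differs from raw-spectral-space "
                f"nearest class {spectral_winner!r}; the decision is made in "
                f"feature space")
    radar = radar_table(q, nearest_spectra, grid, bands=bands)
    return Explanation(query_id, winner, per_class, radar, note)


@dataclass
class VoronoiMap:
    sample_coords: np.ndarray       # (n, 2) PCA projection of all samples
    prototype_coords: np.ndarray    # (m, 2)
    assignment_2d: np.ndarray       # nearest projected prototype per sample
    voronoi: object | None          # scipy.spatial.Voronoi, or None
    disagreement_rate: float | None  # 2-D vs full-dim nearest prototype
    notice: str = ""


def voronoi_projection(prototype_features: np.ndarray,
                       all_features: np.ndarray) -> VoronoiMap:
    """Project everything to the top-2 principal axes of ``all_features`` and
    tessellate the projected prototypes.

    With fewer than 3 prototypes (or a degenerate qhull input) coordinates are
    still returned, with a notice and no cell geometry. The fraction of
    samples whose 2-D cell disagrees with their full-dimensional nearest
    prototype is always reported.
    """
    from sklearn.decomposition import PCA

    P = np.atleast_2d(np.asarray(prototype_features, dtype=float))
    X = np.atleast_2d(np.asarray(all_features, dtype=float))
    pca = PCA(n_components=2, random_state=0)
    coords = pca.fit_transform(X)
    pcoords = pca.transform(P)
    assignment_2d = cdist(coords, pcoords, "sqeuclidean").argmin(axis=1)
    assignment_full = cdist(X, P, "sqeuclidean").argmin(axis=1)
    disagree = float(np.mean(assignment_2d != assignment_full))
    vor, notice = None, ""
    if len(P) < 3:
        notice = f"only {len(P)} prototypes: cell polygons omitted"
    else:
        from scipy.spatial import Voronoi
        try:
            vor = Voronoi(pcoords)
        except Exception as exc:  # degenerate geometry (collinear, duplicates)
            notice = f"tessellation unavailable: {exc}"
    return VoronoiMap(coords, pcoords, assignment_2d, vor, disagree, notice)


# ---------------------------------------------------------------------------
# figure rendering (best effort; the tables above are the tested surface)

def plot_radar(table: pd.DataFrame, ax=None, title: str = ""):
    """Polar radar plot of a band-distance table (query at the origin)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    angles = np.linspace(0, 2 * np.pi, len(table.index), endpoint=False)
    closed = np.concatenate([angles, angles[:1]])
    for col in table.columns:
        vals = table[col].to_numpy()
        ax.plot(closed, np.concatenate([vals, vals[:1]]), label=col)
    ax.set_xticks(angles)
    ax.set_xticklabels(table.index, fontsize=6)
    if title:
        ax.set_title(title)
    ax.legend(fontsize=7, loc="upper right", bbox_to_anchor=(1.3, 1.1))
    return ax


def plot_voronoi(vmap: VoronoiMap, labels=None, ax=None):
    """Scatter of projected samples with the prototype tessellation overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if vmap.voronoi is not None:
        from scipy.spatial import voronoi_plot_2d
        voronoi_plot_2d(vmap.voronoi, ax=ax, show_points=False,
                        show_vertices=False, line_alpha=0.6)
    color = vmap.assignment_2d if labels is None else \
        pd.factorize(np.asarray(labels))[0]
    ax.scatter(vmap.sample_coords[:, 0], vmap.sample_coords[:, 1],
               c=color, s=12, alpha=0.6, cmap="tab10")
    ax.scatter(vmap.prototype_coords[:, 0], vmap.prototype_coords[:, 1],
               marker="*", s=160, c="black", label="prototypes")
    ax.legend(fontsize=8)
    return ax
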
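"""Prototype identification: clustering in feature space + medoid selection.

Prototypes are always *real training samples*: every clustering method first
produces centroids (or density peaks), and the nearest training row to each
centroid is then selected, medoid-style. Three clustering back-ends are
built in — k-means (Lloyd with kmeans++ restarts and a logged inertia
trajectory), mean-shift, and a density/typicality peak selector (ADP-style,
Cauchy density, greedy radius exclusion) — plus a plugin hook for anything
else that maps a feature matrix to centroids.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "ClusterConfig",
    "PrototypeSet",
    "cluster_features",
    "kmeans_lloyd",
    "adp_select",
    "select_medoids",
    "identify_prototypes",
    "label_prototypes",
]


@dataclass
class ClusterConfig:
    """Which clustering method identifies centroids, and its knobs."""

    method: str = "kmeans"  # kmeans | meanshift | adp | plugin
    k: int | None = 3
    bandwidth: float | str = "auto"
    adp_radius_factor: float = 1.0
    seed: int = 0
    plugin: object | None = None  # callable(features) -> centroids

    def __post_init__(self):
        if self.method not in ("kmeans", "meanshift", "adp", "plugin"):
            raise ValueError(f"unknown clustering method {self.method!r}")
        if self.method == "kmeans" and (self.k is None or self.k < 1):
            raise ValueError("kmeans requires k >= 1")
        if self.method == "meanshift" and self.bandwidth != "auto" and self.bandwidth <= 0:
            raise ValueError("meanshift bandwidth must be positive")
        if self.adp_radius_factor <= 0:
            raise ValueError("adp_radius_factor must be positive")

    def describe(self) -> dict:
        return {"method": self.method, "k": self.k, "bandwidth": self.bandwidth,
                "adp_radius_factor": self.adp_radius_factor, "seed": self.seed}


@dataclass
class PrototypeSet:
    """Selected prototypes: training-sample indices, their feature vectors,
    optional class labels, and the provenance of the selection."""

    indices: np.ndarray
    features: np.ndarray
    labels: list[str] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.features = np.asarray(self.features, dtype=float)
        if len(self.indices) != len(self.features):
            raise ValueError("indices and features length mismatch")
        if self.labels is not None and len(self.labels) != len(self.indices):
            raise ValueError("labels length mismatch")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def classes(self) -> list[str]:
        if self.labels is None:
            raise ValueError("prototypes are unlabeled; call label_prototypes first")
        return list(dict.fromkeys(self.labels))

    def save(self, path_prefix: str | Path) -> None:
        """JSON sidecar (indices, labels, provenance) + CSV feature matrix."""
        prefix = Path(path_prefix)
        meta = {"indices": self.indices.tolist(), "labels": self.labels,
                "provenance": self.provenance}
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))
        np.savetxt(prefix.with_suffix(".features.csv"), self.features,
                   delimiter=",", fmt="%.10g")

    @classmethod
    def load(cls, path_prefix: str | Path) -> "PrototypeSet":
        prefix = Path(path_prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        features = np.atleast_2d(np.loadtxt(prefix.with_suffix(".features.csv"),
                                            delimiter=","))
        return cls(np.array(meta["indices"]), features, meta["labels"],
                   meta.get("provenance", {}))


# ---------------------------------------------------------------------------
# clustering back-ends

def kmeans_lloyd(features: np.ndarray, k: int, seed: int = 0, n_restarts: int = 10,
                 max_iter: int = 100, tol: float = 1e-7
                 ) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Lloyd's k-means with kmeans++ init and seeded restarts.

    Returns ``(centroids, assignment, inertia_trajectory)`` of the best
    restart; the trajectory is the within-cluster sum of squares after each
    Lloyd iteration (non-increasing by construction).
    """
    X = np.asarray(features, dtype=float)
    n = len(X)
    if k > n:
        raise ValueError(f"k={k} exceeds number of rows {n}")
    if k > 1 and np.all(X == X[0]):
        raise ValueError(f"all {n} rows are identical; k={k} clustering is degenerate")
    best = None
    root = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4B]))
    for _ in range(n_restarts):
        rng = np.random.default_rng(root.integers(2**31))
        centroids = _kmeanspp_init(X, k, rng)
        trajectory: list[float] = []
        assign = None
        for _ in range(max_iter):
            d2 = cdist(X, centroids, "sqeuclidean")
            assign = d2.argmin(axis=1)
            inertia = float(d2[np.arange(n), assign].sum())
            trajectory.append(inertia)
            new_centroids = centroids.copy()
            for j in range(k):
                members = X[assign == j]
                if len(members):
                    new_centroids[j] = members.mean(axis=0)
                else:  # re-seed an empty cluster at the worst-fit point
                    new_centroids[j] = X[d2[np.arange(n), assign].argmax()]
            if np.allclose(new_centroids, centroids, atol=tol, rtol=0.0):
                break
            centroids = new_centroids
        if best is None or trajectory[-1] < best[2][-1]:
            best = (centroids, assign, trajectory)
    return best


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = len(X)
    centroids = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = cdist(X, np.asarray(centroids), "sqeuclidean").min(axis=1)
        total = d2.sum()
        if total == 0:
            centroids.append(X[rng.integers(n)])
            continue
        centroids.append(X[rng.choice(n, p=d2 / total)])
    return np.asarray(centroids, dtype=float)


def adp_select(features: np.ndarray, radius_factor: float = 1.0) -> np.ndarray:
    """Density/typicality peak selection (autonomous data partitioning style).

    Density D(x) = 1 / (1 + ||x - mu||^2 / sigma^2), with mu the sample mean
    and sigma^2 the mean squared distance to mu; typicality is D normalised
    over the sample. Rows are ranked by typicality (ties broken by row index)
    and greedily accepted as prototypes if they are farther than
    ``radius_factor * sigma`` from every already-accepted prototype. At least
    one prototype (the global typicality peak) is always returned.

    Returned centroids are actual data rows, so medoid selection is a no-op
    on them by construction.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    mu = X.mean(axis=0)
    d2 = np.square(X - mu).sum(axis=1)
    sigma2 = d2.mean()
    if sigma2 == 0:  # zero spread: one prototype, the (identical) first row
        return X[:1].copy()
    density = 1.0 / (1.0 + d2 / sigma2)
    typicality = density / density.sum()
    order = np.lexsort((np.arange(len(X)), -typicality))
    radius = radius_factor * np.sqrt(sigma2)
    accepted: list[int] = []
    for i in order:
        if not accepted:
            accepted.append(i)
            continue
        dists = np.sqrt(np.square(X[accepted] - X[i]).sum(axis=1))
        if np.all(dists > radius):
            accepted.append(i)
    return X[np.array(accepted)]


def _auto_bandwidth(X: np.ndarray, seed: int) -> float:
    """Median pairwise distance / 2, on a subsample when n is large."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBA]))
    sub = X if len(X) <= 500 else X[rng.choice(len(X), 500, replace=False)]
    d = cdist(sub, sub)
    med = float(np.median(d[np.triu_indices(len(sub), k=1)]))
    return med / 2.0 if med > 0 else 1.0


def cluster_features(features: np.ndarray, cfg: ClusterConfig
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Cluster rows of ``features``; returns (centroids, per-row assignment).

    The assignment is always the nearest centroid under l2, regardless of the
    method that produced the centroids.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if len(X) < 1:
        raise ValueError("need at least one feature row")
    if cfg.method == "kmeans":
        centroids, _, _ = kmeans_lloyd(X, cfg.k, seed=cfg.seed)
    elif cfg.method == "meanshift":
        from sklearn.cluster import MeanShift
        bw = _auto_bandwidth(X, cfg.seed) if cfg.bandwidth == "auto" else float(cfg.bandwidth)
        centroids = MeanShift(bandwidth=bw).fit(X).cluster_centers_
    elif cfg.method == "adp":
        centroids = adp_select(X, cfg.adp_radius_factor)
    else:
        if cfg.plugin is None:
            raise ValueError("method 'plugin' requires cfg.plugin to be a callable")
        centroids = np.atleast_2d(np.asarray(cfg.plugin(X), dtype=float))
    assignment = cdist(X, centroids, "sqeuclidean").argmin(axis=1)
    return centroids, assignment


def select_medoids(features: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Index of the nearest real sample to each centroid (ties: lowest index);
    duplicate winners are collapsed, preserving first-seen order."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    C = np.atleast_2d(np.asarray(centroids, dtype=float))
    if len(C) == 0:
        raise ValueError("centroids must be nonempty")
    winners = cdist(C, X, "sqeuclidean").argmin(axis=1)  # argmin takes lowest index on ties
    return np.array(list(dict.fromkeys(winners.tolist())), dtype=int)


def identify_prototypes(features: np.ndarray, labels=None,
                        cfg: ClusterConfig | None = None) -> PrototypeSet:
    """Cluster and medoid-select prototypes.

    Labeled mode clusters each class separately and the medoids inherit the
    class label. Unlabeled mode clusters all rows together; the resulting
    prototypes carry no labels until :func:`label_prototypes` assigns them
    from a small labeled subset.

    For k-means the requested k is capped at the number of distinct rows
    being clustered (a degenerate feature set — e.g. a collapsed encoder
    mapping everything to one point — then yields a single prototype instead
    of an error).
    """
    cfg = cfg or ClusterConfig()
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if len(X) == 0:
        raise ValueError("features must be nonempty")
    provenance = {"cluster": cfg.describe(), "n_training_rows": len(X)}

    def effective_cfg(rows: np.ndarray) -> ClusterConfig:
        if cfg.method != "kmeans":
            return cfg
        n_distinct = len(np.unique(rows, axis=0))
        k = min(cfg.k, n_distinct, len(rows))
        if k == cfg.k:
            return cfg
        return ClusterConfig("kmeans", k=k, bandwidth=cfg.bandwidth,
                             adp_radius_factor=cfg.adp_radius_factor,
                             seed=cfg.seed)

    if labels is None:
        centroids, _ = cluster_features(X, effective_cfg(X))
        idx = select_medoids(X, centroids)
        return PrototypeSet(idx, X[idx], None, provenance)
    labels = list(labels)
    all_idx: list[int] = []
    all_labels: list[str] = []
    for cls in dict.fromkeys(labels):
        rows = np.flatnonzero([l == cls for l in labels])
        centroids, _ = cluster_features(X[rows], effective_cfg(X[rows]))
        for i in select_medoids(X[rows], centroids):
            all_idx.append(int(rows[i]))
            all_labels.append(cls)
    order = np.arange(len(all_idx))
    idx = np.array(all_idx)[order]
    return PrototypeSet(idx, X[idx], [all_labels[i] for i in order], provenance)


def label_prototypes(protos: PrototypeSet, labeled_features: np.ndarray,
                     labeled_labels) -> PrototypeSet:
    """Name unlabeled prototypes by majority vote of a labeled subset.

    Each labeled sample is assigned to its nearest prototype; every prototype
    takes the majority class of its partition cell (ties and empty cells fall
    back to the class of the single nearest labeled sample).
    """
    L = np.atleast_2d(np.asarray(labeled_features, dtype=float))
    labs = list(labeled_labels)
    d = cdist(L, protos.features, "sqeuclidean")
    nearest_proto = d.argmin(axis=1)
    labels_out: list[str] = []
    for j in range(len(protos)):
        members = [labs[i] for i in np.flatnonzero(nearest_proto == j)]
        if members:
            counts: dict[str, int] = {}
            for m in members:
                counts[m] = counts.get(m, 0) + 1
            labels_out.append(max(counts, key=lambda c: (counts[c], -labs.index(c))))
        else:
            labels_out.append(labs[int(d[:, j].argmin())])
    prov = dict(protos.provenance)
    prov["labeling"] = f"majority vote over {len(L)} labeled samples"
    return PrototypeSet(protos.indices, protos.features, labels_out, prov)
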
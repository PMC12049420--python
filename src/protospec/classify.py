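"""The three decision systems.

* :class:`IdealModel` — nearest-prototype classification in the encoder's
  feature space: the winning label is the class of the prototype with minimal
  squared Euclidean feature distance (winner-takes-all over the negative
  distance; ties go to the lowest prototype index).
* :class:`XdnnModel` — a prototype classifier built from per-class Cauchy
  densities and typicality scores; per-class confidence is the best
  exponential similarity over that class's prototypes, and each class
  contributes one human-readable OR-rule over its prototypes.
* :class:`PcaLdaModel` — the chemometrics baseline: per-feature
  standardisation, PCA (no whitening), then an LDA discriminant projection
  (SVD solver) with nearest-class-mean prediction in discriminant space. It
  consumes preprocessed raw spectra, not encoder features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .prototypes import PrototypeSet, adp_select, select_medoids

__all__ = [
    "IdealModel",
    "IdealPrediction",
    "ideal_predict",
    "XdnnModel",
    "xdnn_fit",
    "xdnn_predict",
    "PcaLdaModel",
    "pca_lda_fit",
    "pca_lda_predict",
]


# ---------------------------------------------------------------------------
# nearest-prototype (IDEAL)

@dataclass
class IdealModel:
    """Nearest-prototype decision rule over a labeled prototype set."""

    prototypes: PrototypeSet
    similarity: str = "none"  # "none" | "exp_neg_sq_dist"

    def __post_init__(self):
        if self.prototypes.labels is None:
            raise ValueError("IdealModel needs labeled prototypes")
        if len(self.prototypes.classes) < 2:
            raise ValueError("IdealModel needs prototypes from >= 2 classes")
        if self.similarity not in ("none", "exp_neg_sq_dist"):
            raise ValueError(f"unknown similarity transform {self.similarity!r}")

    @property
    def class_vocab(self) -> list[str]:
        return self.prototypes.classes

    def predict(self, query_features: np.ndarray) -> "IdealPrediction":
        return ideal_predict(query_features, self)


@dataclass
class IdealPrediction:
    labels: list[str]
    winner_index: np.ndarray       # prototype index (into the prototype set)
    distances: np.ndarray          # (n_queries, n_prototypes) l2 distances
    similarities: np.ndarray | None = None


def ideal_predict(query_features: np.ndarray, model: IdealModel) -> IdealPrediction:
    """Label each query by its nearest prototype's class.

    Distances are plain l2 in feature space; the winner is the argmin (ties:
    lowest prototype index). When the model's similarity transform is
    ``exp_neg_sq_dist``, similarities exp(-d^2) in (0, 1] are also returned.
    """
    Q = np.atleast_2d(np.asarray(query_features, dtype=float))
    P = model.prototypes.features
    if Q.shape[1] != P.shape[1]:
        raise ValueError(f"feature dimension mismatch: queries {Q.shape[1]}, "
                         f"prototypes {P.shape[1]}")
    d2 = cdist(Q, P, "sqeuclidean")
    winner = d2.argmin(axis=1)
    labels = [model.prototypes.labels[i] for i in winner]
    sims = np.exp(-d2) if model.similarity == "exp_neg_sq_dist" else None
    return IdealPrediction(labels, winner, np.sqrt(d2), sims)


# ---------------------------------------------------------------------------
# density/typicality prototype classifier (xDNN)

@dataclass
class XdnnModel:
    class_vocab: list[str]
    class_means: np.ndarray           # (C, d)
    class_scatter: np.ndarray         # (C,) sigma_c^2
    prototypes: dict[str, np.ndarray]  # class -> (m_c, d) prototype features
    prototype_indices: dict[str, np.ndarray]  # class -> training-row indices
    typicality: dict[str, np.ndarray]  # class -> per-training-row typicality
    rules: dict[str, str]
    flags: list[str] = field(default_factory=list)

    def density(self, X: np.ndarray, cls: str) -> np.ndarray:
        """Cauchy density D_c(x) = 1 / (1 + ||x - mu_c||^2 / sigma_c^2)."""
        c = self.class_vocab.index(cls)
        d2 = np.square(np.atleast_2d(X) - self.class_means[c]).sum(axis=1)
        return 1.0 / (1.0 + d2 / self.class_scatter[c])

    def predict(self, X: np.ndarray):
        return xdnn_predict(X, self)


def xdnn_fit(features: np.ndarray, labels, radius_factor: float = 1.0,
             class_vocab=None) -> XdnnModel:
    """Fit per-class density/typicality layers and select prototype peaks.

    Per class: mu_c and sigma_c^2 (mean squared distance to mu_c) define the
    Cauchy density; typicality is the density normalised over the class's
    training rows (sums to 1). Prototypes are the typicality peaks found by
    :func:`protospec.prototypes.adp_select` (which returns real rows, i.e.
    medoid-constrained). A single-sample class becomes its own prototype with
    sigma_c^2 borrowed from the global mean scatter (flagged).
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    labels = list(labels)
    vocab = list(class_vocab) if class_vocab else list(dict.fromkeys(labels))
    if len(vocab) < 2:
        raise ValueError(f"need >= 2 classes, got {len(vocab)}")
    y = np.array([vocab.index(l) for l in labels])
    global_scatter = np.square(X - X.mean(axis=0)).sum(axis=1).mean()
    means, scatters = [], []
    protos, proto_idx, typ, rules = {}, {}, {}, {}
    flags: list[str] = []
    for c, cls in enumerate(vocab):
        rows = np.flatnonzero(y == c)
        Xc = X[rows]
        mu = Xc.mean(axis=0)
        d2 = np.square(Xc - mu).sum(axis=1)
        sigma2 = d2.mean()
        if len(rows) == 1 or sigma2 == 0:
            sigma2 = global_scatter if global_scatter > 0 else 1.0
            flags.append(f"class {cls!r}: degenerate scatter, using global mean scatter")
            centroids = Xc[:1]
        else:
            centroids = adp_select(Xc, radius_factor)
        local_idx = select_medoids(Xc, centroids)
        means.append(mu)
        scatters.append(sigma2)
        protos[cls] = Xc[local_idx]
        proto_idx[cls] = rows[local_idx]
        density = 1.0 / (1.0 + d2 / sigma2)
        typ[cls] = density / density.sum()
        names = [f"p{int(i)}" for i in rows[local_idx]]
        rules[cls] = "IF " + " OR ".join(f"x ~ {n}" for n in names) + f" THEN {cls!r}"
    return XdnnModel(vocab, np.stack(means), np.array(scatters),
                     protos, proto_idx, typ, rules, flags)


def xdnn_predict(query_features: np.ndarray, model: XdnnModel
                 ) -> tuple[list[str], np.ndarray, list[str]]:
    """Winner-takes-all over per-class confidences.

    Confidence lambda_c(x) = max over class-c prototypes of
    exp(-||x - p||^2 / sigma_c^2); the label is the argmax class (ties go to
    the class earlier in the vocabulary). Returns (labels, per-class
    confidence matrix, firing rule per query).
    """
    Q = np.atleast_2d(np.asarray(query_features, dtype=float))
    dim = model.class_means.shape[1]
    if Q.shape[1] != dim:
        raise ValueError(f"feature dimension mismatch: queries {Q.shape[1]}, model {dim}")
    conf = np.empty((len(Q), len(model.class_vocab)))
    best_proto = np.empty((len(Q), len(model.class_vocab)), dtype=int)
    for c, cls in enumerate(model.class_vocab):
        d2 = cdist(Q, model.prototypes[cls], "sqeuclidean")
        s = np.exp(-d2 / model.class_scatter[c])
        conf[:, c] = s.max(axis=1)
        best_proto[:, c] = s.argmax(axis=1)
    winner = conf.argmax(axis=1)  # first max wins: earlier class on ties
    labels = [model.class_vocab[c] for c in winner]
    firing = [model.rules[model.class_vocab[c]] for c in winner]
    return labels, conf, firing


# ---------------------------------------------------------------------------
# PCA/LDA baseline

@dataclass
class PcaLdaModel:
    mu: np.ndarray
    sigma: np.ndarray
    zero_var: np.ndarray
    pca: object
    lda: object
    class_vocab: list[str]
    class_means_disc: np.ndarray  # class means in discriminant space
    n_components: int
    train_fingerprint_: str | None = None

    def transform(self, spectra_matrix: np.ndarray) -> np.ndarray:
        from .preprocess import apply_standardization
        Z = apply_standardization(np.atleast_2d(spectra_matrix), self.mu,
                                  self.sigma, self.zero_var)
        return self.lda.transform(self.pca.transform(Z))

    def predict(self, spectra_matrix: np.ndarray) -> list[str]:
        return pca_lda_predict(spectra_matrix, self)


def pca_lda_fit(spectra_matrix: np.ndarray, labels, n_components: int,
                standardize: bool = True, class_vocab=None) -> PcaLdaModel:
    """Standardise, reduce to ``n_components`` principal axes (whiten=False),
    then fit the LDA discriminant (SVD solver) on the projected training data.

    ``standardize=False`` assumes the caller already standardised the matrix
    (a warning is raised if the column means look far from zero).
    """
    from sklearn.decomposition import PCA
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from .preprocess import standardize_features

    X = np.atleast_2d(np.asarray(spectra_matrix, dtype=float))
    labels = list(labels)
    vocab = list(class_vocab) if class_vocab else list(dict.fromkeys(labels))
    if not 1 <= n_components <= 100:
        raise ValueError(f"n_components must be in [1, 100], got {n_components}")
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if n_components > max_rank:
        raise ValueError(f"n_components={n_components} exceeds achievable rank "
                         f"{max_rank} for a {X.shape[0]}x{X.shape[1]} matrix")
    if standardize:
        Z, mu, sigma, zero_var = standardize_features(X)
    else:
        mu = np.zeros(X.shape[1])
        sigma = np.ones(X.shape[1])
        zero_var = np.zeros(X.shape[1], dtype=bool)
        Z = X
        col_means = np.abs(X.mean(axis=0))
        if col_means.mean() > 0.5:
            warnings.warn("input does not look standardized (column means far "
                          "from 0); pass standardize=True or standardize first",
                          stacklevel=2)
    pca = PCA(n_components=n_components, whiten=False, svd_solver="auto",
              random_state=0)
    T = pca.fit_transform(Z)
    lda = LinearDiscriminantAnalysis(solver="svd")
    y = np.array([vocab.index(l) for l in labels])
    lda.fit(T, y)
    D = lda.transform(T)
    class_means = np.stack([D[y == c].mean(axis=0) for c in range(len(vocab))])
    return PcaLdaModel(mu, sigma, zero_var, pca, lda, vocab, class_means,
                       n_components)


def pca_lda_predict(spectra_matrix: np.ndarray, model: PcaLdaModel) -> list[str]:
    """Nearest class mean in the LDA discriminant space; deterministic."""
    D = model.transform(spectra_matrix)
    d2 = cdist(D, model.class_means_disc, "sqeuclidean")
    return [model.class_vocab[i] for i in d2.argmin(axis=1)]
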
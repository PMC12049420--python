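"""Cross-validation harness with leakage guarding.

``run_cv`` drives stratified k-fold evaluation of any pipeline expressed as a
fit function ``fit_fn(X_train, y_train) -> model``. The model must expose
``predict(X) -> labels`` and a ``train_fingerprint_`` attribute equal to
:func:`fingerprint` of exactly the data it was fitted on — the harness
recomputes the fingerprint of each fold's training rows and hard-errors on
any mismatch, so a model fitted outside the fold (or on the full dataset)
cannot slip through.

Fold accuracies are summarised as mean +/- a Student-t 95% interval
half-width over folds.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CVConfig",
    "CVResult",
    "LeakageError",
    "fingerprint",
    "kfold_split",
    "run_cv",
    "experiment_grid",
]


class LeakageError(RuntimeError):
    """A model artifact was fitted on data outside the fold's training split."""


@dataclass
class CVConfig:
    """Fold count (10 is the prototype-classifier convention, 6 the PCA/LDA
    one), stratification flag, and the seed that fixes the fold shuffle."""

    n_folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2:
            raise ValueError(f"n_folds must be >= 2, got {self.n_folds}")


@dataclass
class CVResult:
    fold_accuracies: list[float]
    mean_accuracy: float
    ci_half_width: float
    confusion_matrices: list[np.ndarray]
    class_vocab: list[str]
    provenance: dict = field(default_factory=dict)

    @property
    def max_accuracy(self) -> float:
        return max(self.fold_accuracies)


def fingerprint(X: np.ndarray, y) -> str:
    """Stable digest of a training set (rows + labels)."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(np.asarray(X, dtype=np.float64)).tobytes())
    h.update("\x1f".join(str(l) for l in y).encode())
    return h.hexdigest()


def kfold_split(labels, cfg: CVConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic (seeded) k-fold partition of the sample indices.

    Stratified folds preserve class proportions within one sample. A class
    smaller than the fold count cannot be stratified and raises with a
    suggestion to lower ``n_folds``.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    labels = list(labels)
    n = len(labels)
    if cfg.n_folds > n:
        raise ValueError(f"n_folds={cfg.n_folds} exceeds n_samples={n}")
    if cfg.stratified:
        counts: dict[str, int] = {}
        for l in labels:
            counts[l] = counts.get(l, 0) + 1
        small = {c: k for c, k in counts.items() if k < cfg.n_folds}
        if small:
            raise ValueError(
                f"classes smaller than n_folds={cfg.n_folds}: {small}; "
                f"use at most {min(small.values())} folds")
        splitter = StratifiedKFold(cfg.n_folds, shuffle=True, random_state=cfg.seed)
        split = splitter.split(np.zeros(n), labels)
    else:
        splitter = KFold(cfg.n_folds, shuffle=True, random_state=cfg.seed)
        split = splitter.split(np.zeros(n))
    return [(np.asarray(tr), np.asarray(te)) for tr, te in split]


def run_cv(X: np.ndarray, labels, cfg: CVConfig, fit_fn,
           class_vocab=None, provenance: dict | None = None) -> CVResult:
    """Fit ``fit_fn`` on each fold's training rows only and score the test rows.

    Every artifact (standardisation statistics, clustering, finetuning, ...)
    must be fitted inside ``fit_fn``; the returned model's
    ``train_fingerprint_`` is checked against the fold's training data.
    """
    from sklearn.metrics import confusion_matrix

    X = np.asarray(X)
    labels = np.asarray(list(labels), dtype=object)
    vocab = list(class_vocab) if class_vocab else list(dict.fromkeys(labels))
    folds = kfold_split(labels, cfg)
    accs, cms = [], []
    for tr, te in folds:
        model = fit_fn(X[tr], labels[tr])
        expected = fingerprint(X[tr], labels[tr])
        got = getattr(model, "train_fingerprint_", None)
        if got is None:
            raise LeakageError(
                "fitted model carries no train_fingerprint_; the pipeline must "
                "stamp fingerprint(X_train, y_train) at fit time")
        if got != expected:
            raise LeakageError(
                "model was fitted on data other than this fold's training split")
        pred = np.asarray(list(model.predict(X[te])), dtype=object)
        accs.append(float(np.mean(pred == labels[te])))
        cms.append(confusion_matrix(labels[te], pred, labels=vocab))
    k = len(accs)
    mean = float(np.mean(accs))
    sd = float(np.std(accs, ddof=1)) if k > 1 else 0.0
    half = float(stats.t.ppf(0.975, k - 1) * sd / np.sqrt(k)) if k > 1 else 0.0
    prov = {"n_folds": cfg.n_folds, "stratified": cfg.stratified, "seed": cfg.seed}
    prov.update(provenance or {})
    return CVResult(accs, mean, half, cms, vocab, prov)


def experiment_grid(X: np.ndarray, labels, cells: dict[str, object],
                    cfg: CVConfig) -> pd.DataFrame:
    """One cross-validated result row per named pipeline cell.

    ``cells`` maps a cell name (e.g. ``"ideal/kmeans/full"``) to its fit
    function. Returns a table with mean accuracy, 95% interval half-width and
    the best fold, in the order given.
    """
    rows = []
    for name, fit_fn in cells.items():
        res = run_cv(X, labels, cfg, fit_fn, provenance={"cell": name})
        rows.append({"cell": name, "mean_accuracy": res.mean_accuracy,
                     "ci_half_width": res.ci_half_width,
                     "max_accuracy": res.max_accuracy,
                     "n_folds": cfg.n_folds})
    return pd.DataFrame(rows)
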
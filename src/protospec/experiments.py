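"""End-to-end study routines at desk scale.

These functions wire the whole pipeline together on synthetic data — source
domain pretraining, the three transfer regimes, prototype identification,
nearest-prototype classification, the PCA/LDA baseline, and the radar-band
localization analysis. They are what the acceptance script runs and what the
end-to-end tests assert on.

Scale: the source domain uses 10 narrow-band classes x 200 spectra with 30
pretraining epochs; the target domain uses the two broad-band classes with
30 training and 100 test spectra per class; finetuning (and from-scratch
training) runs 50 epochs. These sizes keep a full run in the minutes range
on one CPU while preserving the qualitative ordering of the transfer
regimes.
"""

from __future__ import annotations

import numpy as np

from . import synthetic
from .classify import IdealModel, ideal_predict, pca_lda_fit, xdnn_fit
from .encoder import EncoderModel, TrainConfig, build_encoder, finetune, train_source
from .evaluate import CVConfig, fingerprint, run_cv
from .interpret import partition_bands, radar_table
from .preprocess import PreprocessConfig, preprocess_dataset
from .prototypes import ClusterConfig, identify_prototypes

__all__ = [
    "pretrain_source_encoder",
    "clone_encoder",
    "prototype_accuracy",
    "run_transfer_benchmark",
    "run_band_localization",
    "run_pcalda_cv",
    "run_prototype_cv",
    "make_ideal_fit_fn",
    "make_xdnn_fit_fn",
    "make_pcalda_fit_fn",
]

N_SOURCE_CLASSES = 10
N_SOURCE_PER_CLASS = 200
PRETRAIN_EPOCHS = 30
N_TARGET_TRAIN = 30   # per class
N_TARGET_TEST = 100   # per class
FINETUNE_EPOCHS = 50
N_SEEDS = 5


def _sub(seed: int, *tags: int) -> int:
    """Derive an independent 31-bit seed from a base seed and a tag path."""
    return int(np.random.SeedSequence([int(seed), *tags]).generate_state(1)[0] % (2**31))


def pretrain_source_encoder(seed: int, epochs: int = PRETRAIN_EPOCHS,
                            n_per_class: int = N_SOURCE_PER_CLASS
                            ) -> tuple[EncoderModel, float]:
    """Pretrain the default encoder on the narrow-band source domain.

    Returns the trained model and its training accuracy scored in inference
    mode (in-epoch history accuracies understate the fit because dropout is
    active there).
    """
    recipes = list(synthetic.mineral_recipes().values())[:N_SOURCE_CLASSES]
    data = synthetic.generate_dataset(recipes, n_per_class, seed=_sub(seed, 1))
    X, _ = preprocess_dataset(data, PreprocessConfig())
    model = build_encoder(seed=_sub(seed, 2))
    cfg = TrainConfig(mode="source_pretrain", epochs=epochs, learning_rate=0.01,
                      batch_size=20, seed=_sub(seed, 3))
    train_source(model, X, data.labels, cfg)
    return model, model.head_accuracy(X, data.labels)


def clone_encoder(model: EncoderModel) -> EncoderModel:
    """A fresh encoder with identical parameters (head excluded)."""
    out = build_encoder(model.config, seed=model.seed)
    state = {k: v.copy() for k, v in model.state_dict().items()
             if not k.startswith("head.")}
    out.load_state_dict(state)
    return out


def _target_split(seed: int, noise_sd: float = 0.02):
    recipes = synthetic.ivory_recipes(noise_sd)
    train = synthetic.generate_dataset(recipes, N_TARGET_TRAIN, seed=_sub(seed, 10))
    test = synthetic.generate_dataset(recipes, N_TARGET_TEST, seed=_sub(seed, 11))
    cfg = PreprocessConfig()
    Xtr, grid = preprocess_dataset(train, cfg)
    Xte, _ = preprocess_dataset(test, cfg)
    return Xtr, train.labels, Xte, test.labels, grid


def prototype_accuracy(encoder: EncoderModel, Xtr, ytr, Xte, yte,
                       cluster: ClusterConfig | None = None) -> float:
    """Frozen-encoder nearest-prototype accuracy on a train/test split."""
    cluster = cluster or ClusterConfig(method="kmeans", k=3)
    Ftr = encoder.extract_features(Xtr)
    Fte = encoder.extract_features(Xte)
    protos = identify_prototypes(Ftr, ytr, cluster)
    pred = ideal_predict(Fte, IdealModel(protos))
    return float(np.mean(np.asarray(pred.labels) == np.asarray(yte)))


def run_transfer_benchmark(seed: int, n_seeds: int = N_SEEDS,
                           pretrained: EncoderModel | None = None) -> dict:
    """Compare the three training regimes on the two-class target domain.

    For each of ``n_seeds`` target resamplings: (a) full finetuning of the
    source-pretrained encoder, (b) end-to-end training from scratch on the
    small target training set, (c) the frozen pretrained encoder — each
    followed by the same k-means prototype identification and
    nearest-prototype classification of the held-out test spectra.
    """
    if pretrained is None:
        pretrained, source_acc = pretrain_source_encoder(seed)
    else:
        source_acc = pretrained.history[-1]["accuracy"] if pretrained.history else float("nan")
    finetune_accs, scratch_accs, frozen_accs = [], [], []
    for i in range(n_seeds):
        Xtr, ytr, Xte, yte, _ = _target_split(_sub(seed, 20, i))
        # (a) pretrain -> full finetune
        ft = clone_encoder(pretrained)
        finetune(ft, Xtr, ytr, TrainConfig(
            mode="full", epochs=FINETUNE_EPOCHS, learning_rate=0.001,
            batch_size=20, seed=_sub(seed, 21, i)))
        finetune_accs.append(prototype_accuracy(ft, Xtr, ytr, Xte, yte))
        # (b) end-to-end from scratch on the target training set alone
        scratch = build_encoder(seed=_sub(seed, 22, i))
        train_source(scratch, Xtr, ytr, TrainConfig(
            mode="source_pretrain", epochs=FINETUNE_EPOCHS, learning_rate=0.01,
            batch_size=20, seed=_sub(seed, 23, i)))
        scratch_accs.append(prototype_accuracy(scratch, Xtr, ytr, Xte, yte))
        # (c) frozen pretrained features, prototypes only
        frozen_accs.append(prototype_accuracy(pretrained, Xtr, ytr, Xte, yte))
    return {
        "source_train_accuracy": float(source_acc),
        "finetune_accuracies": finetune_accs,
        "scratch_accuracies": scratch_accs,
        "frozen_accuracies": frozen_accs,
        "finetune_mean": float(np.mean(finetune_accs)),
        "scratch_mean": float(np.mean(scratch_accs)),
        "frozen_mean": float(np.mean(frozen_accs)),
        "n_seeds": n_seeds,
        "pretrained_encoder": pretrained,
    }


def run_band_localization(seed: int, encoder: EncoderModel,
                          noise_sd: float = 0.02) -> dict:
    """Does the explanation localize the class difference to the 960 band?

    With two classes differing only in the 960 cm^-1 band, classify the test
    spectra with the frozen encoder + nearest prototypes, then for every
    correctly classified query compute the 16-band radar table against each
    class's nearest prototype and test whether the band with the largest
    distance gap (other-class minus own-class) is the one containing
    960 cm^-1.
    """
    Xtr, ytr, Xte, yte, grid = _target_split(_sub(seed, 30), noise_sd)
    Ftr = encoder.extract_features(Xtr)
    Fte = encoder.extract_features(Xte)
    protos = identify_prototypes(Ftr, ytr, ClusterConfig(method="kmeans", k=3))
    model = IdealModel(protos)
    pred = ideal_predict(Fte, model)
    correct = np.asarray(pred.labels) == np.asarray(yte)
    bands = partition_bands(grid, 16)
    band_960 = next(i for i, (lo, hi) in enumerate(bands) if lo <= 960.0 < hi)
    localized = 0
    n_checked = 0
    for qi in np.flatnonzero(correct):
        own = pred.labels[qi]
        nearest = {}
        for cls in model.class_vocab:
            pos = np.flatnonzero([l == cls for l in protos.labels])
            best = pos[pred.distances[qi, pos].argmin()]
            nearest[cls] = Xtr[protos.indices[best]]
        table = radar_table(Xte[qi], nearest, grid, bands=bands)
        other = next(c for c in model.class_vocab if c != own)
        gap = table[other].to_numpy() - table[own].to_numpy()
        localized += int(gap.argmax() == band_960)
        n_checked += 1
    return {
        "accuracy": float(correct.mean()),
        "localization_rate": localized / n_checked if n_checked else float("nan"),
        "n_correct": n_checked,
        "n_test": len(yte),
    }


# ---------------------------------------------------------------------------
# cross-validation pipeline factories (all stamp the leakage fingerprint)

class _Wrapped:
    def __init__(self, predict_fn, fp):
        self._predict = predict_fn
        self.train_fingerprint_ = fp

    def predict(self, X):
        return self._predict(X)


def make_ideal_fit_fn(cluster: ClusterConfig | None = None, feature_fn=None):
    """IDEAL pipeline over (optionally encoder-extracted) features."""
    cluster = cluster or ClusterConfig(method="kmeans", k=3)

    def fit(Xtr, ytr):
        fp = fingerprint(Xtr, ytr)
        Ftr = feature_fn(Xtr) if feature_fn else Xtr
        protos = identify_prototypes(Ftr, list(ytr), cluster)
        model = IdealModel(protos)

        def predict(X):
            F = feature_fn(X) if feature_fn else X
            return ideal_predict(F, model).labels

        return _Wrapped(predict, fp)

    return fit


def make_xdnn_fit_fn(radius_factor: float = 1.0, feature_fn=None):
    def fit(Xtr, ytr):
        fp = fingerprint(Xtr, ytr)
        Ftr = feature_fn(Xtr) if feature_fn else Xtr
        model = xdnn_fit(Ftr, list(ytr), radius_factor=radius_factor)

        def predict(X):
            F = feature_fn(X) if feature_fn else X
            return model.predict(F)[0]

        return _Wrapped(predict, fp)

    return fit


def make_pcalda_fit_fn(n_components: int = 10):
    def fit(Xtr, ytr):
        model = pca_lda_fit(Xtr, list(ytr), n_components)
        model.train_fingerprint_ = fingerprint(Xtr, ytr)
        return model

    return fit


def run_pcalda_cv(seed: int, n_components: int = 10, n_folds: int = 6,
                  n_per_class: int = 100) -> dict:
    """Six-fold cross-validated PCA/LDA baseline on raw preprocessed spectra."""
    data = synthetic.generate_dataset(synthetic.ivory_recipes(), n_per_class,
                                      seed=_sub(seed, 40))
    X, _ = preprocess_dataset(data, PreprocessConfig(spectrum_norm="none"))
    res = run_cv(X, data.labels, CVConfig(n_folds=n_folds, seed=_sub(seed, 41)),
                 make_pcalda_fit_fn(n_components))
    return {"mean_accuracy": res.mean_accuracy, "ci_half_width": res.ci_half_width,
            "n_samples": len(data)}


def run_prototype_cv(seed: int, encoder: EncoderModel, n_folds: int = 10,
                     n_per_class: int = 100) -> dict:
    """Ten-fold cross-validated frozen-feature IDEAL/k-means pipeline."""
    data = synthetic.generate_dataset(synthetic.ivory_recipes(), n_per_class,
                                      seed=_sub(seed, 50))
    X, _ = preprocess_dataset(data, PreprocessConfig())
    F = encoder.extract_features(X)  # frozen encoder: label-independent transform
    res = run_cv(F, data.labels, CVConfig(n_folds=n_folds, seed=_sub(seed, 51)),
                 make_ideal_fit_fn(ClusterConfig(method="kmeans", k=3)))
    return {"mean_accuracy": res.mean_accuracy, "ci_half_width": res.ci_half_width,
            "n_samples": len(data)}
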
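"""The 1-D convolutional spectral feature extractor and its training regimes.

The encoder phi(.; theta) maps a fixed-length spectrum (default 950 points)
to a flat feature vector (default 2048 = 128 channels x 16 pooled positions)
through three conv -> batch-norm -> ReLU -> max-pool -> dropout blocks and an
adaptive max-pool. Training uses mini-batch SGD with momentum on a softmax
cross-entropy head (or, optionally, a soft nearest-prototype distance loss).

Three transfer regimes are supported after source-domain pretraining:

* ``full``   — every encoder parameter is finetuned on the target data;
* ``linear`` — only the last conv block trains; earlier blocks are frozen,
  including their batch-norm statistics;
* ``none``   — the encoder is used as-is (frozen feature extractor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn

__all__ = [
    "EncoderConfig",
    "TrainConfig",
    "EncoderModel",
    "ConfigError",
    "build_encoder",
    "train_source",
    "finetune",
    "extract_features",
    "save_encoder",
    "load_encoder",
]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class EncoderConfig:
    channels: tuple[int, ...] = (32, 64, 128)
    kernel_sizes: tuple[int, ...] = (9, 7, 5)
    pool_sizes: tuple[int, ...] = (2, 2, 2)
    final_pool_length: int = 16
    dropout: float = 0.55
    input_length: int = 950
    feature_dim: int = 2048

    def __post_init__(self):
        n = len(self.channels)
        if len(self.kernel_sizes) != n or len(self.pool_sizes) != n:
            raise ConfigError("channels, kernel_sizes and pool_sizes must align")
        if not 0.0 <= self.dropout < 1.0:
            raise ConfigError(f"dropout must be in [0, 1), got {self.dropout}")
        expected = self.channels[-1] * self.final_pool_length
        if self.feature_dim != expected:
            raise ConfigError(
                f"feature_dim {self.feature_dim} != channels[-1] x final_pool_length "
                f"= {expected}")

    @property
    def n_blocks(self) -> int:
        return len(self.channels)


@dataclass
class TrainConfig:
    """Optimisation settings; defaults follow the source-pretraining recipe
    (batch 20, lr 0.01, dropout 0.55, 150 epochs). Finetuning conventionally
    drops the lr to 0.001 and extends to 250 epochs."""

    mode: str = "source_pretrain"  # source_pretrain | full | linear | none
    batch_size: int = 20
    learning_rate: float = 0.01
    epochs: int = 150
    momentum: float = 0.9
    seed: int = 0
    loss: str = "cross_entropy"  # or "prototype_distance"

    def __post_init__(self):
        if self.mode not in ("source_pretrain", "full", "linear", "none"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if self.epochs < 1 and self.mode != "none":
            raise ConfigError(f"epochs must be >= 1, got {self.epochs}")
        if self.loss not in ("cross_entropy", "prototype_distance"):
            raise ConfigError(f"unknown loss {self.loss!r}")


class EncoderModel:
    """Feature extractor plus an optional disposable classification head."""

    def __init__(self, config: EncoderConfig, seed: int):
        self.config = config
        self.seed = seed
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0]))
        self.blocks: list[nn.Sequential] = []
        in_ch = 1
        for i, (ch, k, p) in enumerate(zip(config.channels, config.kernel_sizes,
                                           config.pool_sizes)):
            self.blocks.append(nn.Sequential([
                nn.Conv1d(in_ch, ch, k, rng, needs_input_grad=(i > 0)),
                nn.BatchNorm1d(ch),
                nn.ReLU(),
                nn.MaxPool1d(p),
                nn.Dropout(config.dropout),
            ]))
            in_ch = ch
        self.pool = nn.AdaptiveMaxPool1d(config.final_pool_length)
        self.flatten = nn.Flatten()
        self.head: nn.Linear | None = None
        self.head_classes: list[str] | None = None
        self.history: list[dict] = []

    # -- structure ---------------------------------------------------------
    def _stack(self) -> nn.Sequential:
        layers: list[nn.Layer] = [*self.blocks, self.pool, self.flatten]
        if self.head is not None:
            layers.append(self.head)
        return nn.Sequential(layers)

    def encoder_parameters(self) -> list[nn.Parameter]:
        return [p for b in self.blocks for p in b.parameters()]

    def attach_head(self, n_classes: int, class_vocab: list[str],
                    rng: np.random.Generator) -> None:
        self.head = nn.Linear(self.config.feature_dim, n_classes, rng)
        self.head_classes = list(class_vocab)

    def set_trainable_blocks(self, trainable: list[bool]) -> None:
        for block, flag in zip(self.blocks, trainable):
            for p in block.parameters():
                p.trainable = flag
            for layer in block.layers:
                if isinstance(layer, nn.BatchNorm1d):
                    layer.freeze_stats = not flag

    # -- inference ---------------------------------------------------------
    def _forward_features(self, x: np.ndarray) -> np.ndarray:
        for block in self.blocks:
            x = block.forward(x)
        return self.flatten.forward(self.pool.forward(x))

    def extract_features(self, spectra: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Map (n, input_length) preprocessed spectra to (n, feature_dim)
        features in inference mode (dropout off, running batch-norm stats)."""
        spectra = np.atleast_2d(np.asarray(spectra, dtype=np.float32))
        if spectra.shape[1] != self.config.input_length:
            raise ValueError(
                f"expected spectra of length {self.config.input_length}, "
                f"got {spectra.shape[1]}")
        stack = nn.Sequential([*self.blocks, self.pool, self.flatten])
        stack.eval()
        out = [stack.forward(spectra[i:i + batch_size, None, :])
               for i in range(0, len(spectra), batch_size)]
        stack.train()
        return np.concatenate(out, axis=0)

    def head_predict(self, spectra: np.ndarray) -> list[str]:
        """Labels from the attached classification head, in inference mode."""
        if self.head is None or self.head_classes is None:
            raise ValueError("no classification head attached; train first")
        logits = self.extract_features(spectra) @ self.head.weight.value \
            + self.head.bias.value
        return [self.head_classes[i] for i in logits.argmax(axis=1)]

    def head_accuracy(self, spectra: np.ndarray, labels) -> float:
        pred = self.head_predict(spectra)
        return float(np.mean([p == l for p, l in zip(pred, labels)]))

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {}
        for i, block in enumerate(self.blocks):
            for key, val in block.state_dict().items():
                state[f"block{i}.{key}"] = val
        if self.head is not None:
            for key, val in self.head.state_dict().items():
                state[f"head.{key}"] = val
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, block in enumerate(self.blocks):
            prefix = f"block{i}."
            block.load_state_dict({k[len(prefix):]: v for k, v in state.items()
                                   if k.startswith(prefix)})
        head_state = {k[5:]: v for k, v in state.items() if k.startswith("head.")}
        if head_state and self.head is not None:
            self.head.load_state_dict(head_state)


def build_encoder(config: EncoderConfig | None = None, seed: int = 0) -> EncoderModel:
    """Deterministically initialised encoder; same seed, same parameters."""
    return EncoderModel(config or EncoderConfig(), seed)


# ---------------------------------------------------------------------------
# training

def _encode_labels(labels, class_vocab=None) -> tuple[np.ndarray, list[str]]:
    vocab = list(class_vocab) if class_vocab else list(dict.fromkeys(labels))
    index = {c: i for i, c in enumerate(vocab)}
    return np.array([index[l] for l in labels]), vocab


def _train_loop(model: EncoderModel, X: np.ndarray, y: np.ndarray,
                cfg: TrainConfig, params: list[nn.Parameter]) -> None:
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x7A]))
    stack = nn.Sequential([*model.blocks, model.pool, model.flatten, model.head])
    stack.bind_dropout_rng(rng)
    stack.train()
    opt = nn.SGD(params, cfg.learning_rate, cfg.momentum)
    n = len(X)
    X = np.asarray(X, dtype=np.float32)[:, None, :]
    prototypes = None
    for epoch in range(cfg.epochs):
        if cfg.loss == "prototype_distance":
            prototypes = _class_mean_prototypes(model, X[:, 0, :], y)
        order = rng.permutation(n)
        total_loss, correct = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            opt.zero_grad()
            if cfg.loss == "cross_entropy":
                logits = stack.forward(xb)
                loss, grad = nn.softmax_cross_entropy(logits, yb)
                stack.backward(grad)
            else:
                feats = nn.Sequential([*model.blocks, model.pool, model.flatten]).forward(xb)
                logits, gfun = _prototype_logits(feats, prototypes)
                loss, glogits = nn.softmax_cross_entropy(logits, yb)
                gfeats = gfun(glogits)
                nn.Sequential([*model.blocks, model.pool, model.flatten]).backward(gfeats)
            opt.step()
            total_loss += loss * len(idx)
            correct += int((logits.argmax(axis=1) == yb).sum())
        model.history.append({"epoch": epoch, "mode": cfg.mode,
                              "loss": total_loss / n, "accuracy": correct / n})
    stack.eval()


def _class_mean_prototypes(model: EncoderModel, X2d: np.ndarray, y: np.ndarray) -> np.ndarray:
    feats = model.extract_features(X2d)
    return np.stack([feats[y == c].mean(axis=0) for c in range(y.max() + 1)])


def _prototype_logits(feats: np.ndarray, prototypes: np.ndarray):
    """Logits = -||f - p_c||^2 per class, with a closure for the feature grad."""
    diff = feats[:, None, :] - prototypes[None, :, :]  # (n, C, d)
    logits = -np.square(diff).sum(axis=2)

    def grad_fn(glogits: np.ndarray) -> np.ndarray:
        return (-2.0 * (glogits[:, :, None] * diff).sum(axis=1)).astype(np.float32)

    return logits, grad_fn


def train_source(model: EncoderModel, X: np.ndarray, labels,
                 cfg: TrainConfig, class_vocab=None) -> EncoderModel:
    """Pretrain the full encoder plus a fresh softmax head on source-domain
    spectra (rows of ``X``, one label per row)."""
    if cfg.mode != "source_pretrain":
        raise ConfigError(f"train_source requires mode='source_pretrain', got {cfg.mode!r}")
    y, vocab = _encode_labels(labels, class_vocab)
    if len(vocab) < 2:
        raise ValueError(f"need >= 2 source classes, got {len(vocab)}")
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x5E]))
    model.attach_head(len(vocab), vocab, rng)
    model.set_trainable_blocks([True] * model.config.n_blocks)
    params = model.encoder_parameters() + model.head.parameters()
    _train_loop(model, X, y, cfg, params)
    return model


def finetune(model: EncoderModel, X: np.ndarray | None, labels,
             cfg: TrainConfig, class_vocab=None) -> EncoderModel:
    """Adapt a pretrained encoder to target-domain data.

    ``full`` trains every block, ``linear`` only the last conv block (earlier
    blocks frozen, frozen batch-norm statistics included), ``none`` returns
    the model untouched (warning if epochs were requested).
    """
    if cfg.mode not in ("full", "linear", "none"):
        raise ConfigError(f"finetune requires mode full|linear|none, got {cfg.mode!r}")
    if cfg.mode == "none":
        if cfg.epochs > 0:
            import warnings
            warnings.warn("finetune(mode='none') ignores the requested epochs; "
                          "the encoder is left unchanged", stacklevel=2)
        return model
    y, vocab = _encode_labels(labels, class_vocab)
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0x5F]))
    model.attach_head(len(vocab), vocab, rng)
    nb = model.config.n_blocks
    trainable = [True] * nb if cfg.mode == "full" else [False] * (nb - 1) + [True]
    model.set_trainable_blocks(trainable)
    params = [p for p in model.encoder_parameters() if p.trainable] + _head_params(model)
    _train_loop(model, X, y, cfg, params)
    model.set_trainable_blocks([True] * nb)  # release freezes for later stages
    return model


def _head_params(model: EncoderModel) -> list[nn.Parameter]:
    return model.head.parameters() if model.head is not None else []


def extract_features(model: EncoderModel, spectra: np.ndarray,
                     batch_size: int = 64) -> np.ndarray:
    """Functional alias for :meth:`EncoderModel.extract_features`."""
    return model.extract_features(spectra, batch_size=batch_size)


# ---------------------------------------------------------------------------
# checkpoints: one .npz archive holding config JSON + parameter arrays

def save_encoder(model: EncoderModel, path) -> None:
    state = model.state_dict()
    meta = {"config": asdict(model.config), "seed": model.seed,
            "head_classes": model.head_classes}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **state)


def load_encoder(path) -> EncoderModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg_dict = meta["config"]
    for key in ("channels", "kernel_sizes", "pool_sizes"):
        cfg_dict[key] = tuple(cfg_dict[key])
    model = EncoderModel(EncoderConfig(**cfg_dict), meta["seed"])
    if meta["head_classes"]:
        rng = np.random.default_rng(0)
        model.attach_head(len(meta["head_classes"]), meta["head_classes"], rng)
    model.load_state_dict(state)
    return model
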
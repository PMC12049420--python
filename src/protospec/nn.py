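"""Minimal numpy layer stack for 1-D convolutional networks.

Implements exactly the pieces the spectral encoder needs — 1-D convolution,
batch normalisation, max pooling (fixed and adaptive), dropout, linear layers,
softmax cross-entropy and SGD with momentum — with hand-written backward
passes. Everything is deterministic given the seeding ``numpy.random.Generator``
and runs in float32.

This is not a general autodiff framework: layers form a simple sequential
chain, ``forward`` caches whatever ``backward`` needs, and ``backward``
consumes the cache of the immediately preceding ``forward`` call.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "AdaptiveMaxPool1d",
    "Dropout",
    "Flatten",
    "Linear",
    "Sequential",
    "SGD",
    "softmax_cross_entropy",
]

DTYPE = np.float32


class Parameter:
    """A trainable array with its gradient accumulator and a freeze flag."""

    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray, trainable: bool = True):
        self.value = np.ascontiguousarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable


class Layer:
    training: bool = True

    def parameters(self) -> list[Parameter]:
        return []

    def train(self) -> None:
        self.training = True

    def eval(self) -> None:
        self.training = False

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def state_dict(self) -> dict[str, np.ndarray]:
        return {}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        pass


class Conv1d(Layer):
    """Valid (no padding) cross-correlation over (N, C_in, L) inputs.

    Implemented as im2col + GEMM. ``needs_input_grad=False`` (set on the
    network's first layer) skips the input-gradient GEMM in backward.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, needs_input_grad: bool = True):
        fan_in = in_channels * kernel_size
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, scale, (out_channels, in_channels, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels))
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.needs_input_grad = needs_input_grad

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n, c, length = x.shape
        k = self.kernel_size
        lout = length - k + 1
        cols = np.lib.stride_tricks.sliding_window_view(x, k, axis=2)  # (N, C_in, L', K)
        cols2 = np.ascontiguousarray(cols.transpose(0, 2, 1, 3)).reshape(n * lout, c * k)
        w2 = self.weight.value.reshape(self.out_channels, c * k).T
        out2 = cols2 @ w2
        out2 += self.bias.value
        self._cache = (cols2, (n, c, length, lout))
        return np.ascontiguousarray(out2.reshape(n, lout, self.out_channels).transpose(0, 2, 1))

    def backward(self, grad):
        cols2, (n, c, length, lout) = self._cache
        k = self.kernel_size
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 1), dtype=DTYPE).reshape(
            n * lout, self.out_channels)
        self.bias.grad += g2.sum(axis=0)
        dw2 = cols2.T @ g2  # (C_in*K, C_out)
        self.weight.grad += dw2.T.reshape(self.out_channels, c, k)
        if not self.needs_input_grad:
            return np.zeros((n, c, length), dtype=DTYPE)
        # input gradient: scatter each kernel tap of (grad @ W^T) back onto the input grid
        w2 = self.weight.value.reshape(self.out_channels, c * k)
        dcols = (g2 @ w2).reshape(n, lout, c, k)
        dx = np.zeros((n, c, length), dtype=DTYPE)
        for tap in range(k):
            dx[:, :, tap:tap + lout] += dcols[:, :, :, tap].transpose(0, 2, 1)
        return dx

    def state_dict(self):
        return {"weight": self.weight.value, "bias": self.bias.value}

    def load_state_dict(self, state):
        self.weight.value = np.ascontiguousarray(state["weight"], dtype=DTYPE)
        self.weight.grad = np.zeros_like(self.weight.value)
        self.bias.value = np.ascontiguousarray(state["bias"], dtype=DTYPE)
        self.bias.grad = np.zeros_like(self.bias.value)


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over (N, C, L) with running statistics.

    ``freeze_stats`` pins the running statistics and makes training-mode
    forward use them (the behaviour frozen blocks keep during partial
    finetuning).
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self.freeze_stats = False

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        x = np.asarray(x, dtype=DTYPE)
        if self.training and not self.freeze_stats:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * inv[:, None]
        self._cache = (xhat, inv, x.shape[0] * x.shape[2],
                       self.training and not self.freeze_stats)
        return self.gamma.value[:, None] * xhat + self.beta.value[:, None]

    def backward(self, grad):
        xhat, inv, m, batch_stats = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        gxhat = grad * self.gamma.value[:, None]
        if not batch_stats:
            return gxhat * inv[:, None]
        # standard batch-norm backward through batch mean/var
        term = gxhat - gxhat.mean(axis=(0, 2), keepdims=True) \
            - xhat * (gxhat * xhat).mean(axis=(0, 2), keepdims=True)
        return term * inv[:, None]

    def state_dict(self):
        return {"gamma": self.gamma.value, "beta": self.beta.value,
                "running_mean": self.running_mean, "running_var": self.running_var}

    def load_state_dict(self, state):
        self.gamma.value = np.ascontiguousarray(state["gamma"], dtype=DTYPE)
        self.gamma.grad = np.zeros_like(self.gamma.value)
        self.beta.value = np.ascontiguousarray(state["beta"], dtype=DTYPE)
        self.beta.grad = np.zeros_like(self.beta.value)
        self.running_mean = np.ascontiguousarray(state["running_mean"], dtype=DTYPE)
        self.running_var = np.ascontiguousarray(state["running_var"], dtype=DTYPE)


class ReLU(Layer):
    def forward(self, x):
        mask = x > 0
        self._cache = mask
        return np.where(mask, x, 0.0).astype(DTYPE, copy=False)

    def backward(self, grad):
        return grad * self._cache


class MaxPool1d(Layer):
    """Non-overlapping max pooling; trailing remainder samples are dropped."""

    def __init__(self, size: int):
        self.size = size

    def forward(self, x):
        n, c, length = x.shape
        s = self.size
        lout = length // s
        xr = x[:, :, : lout * s].reshape(n, c, lout, s)
        if s == 2:
            # fast path: a boolean mask beats argmax/take_along_axis
            right_wins = xr[..., 1] > xr[..., 0]
            idx = right_wins.astype(np.int64)
            out = np.where(right_wins, xr[..., 1], xr[..., 0])
        else:
            idx = xr.argmax(axis=3)
            out = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]
        self._cache = (x.shape, idx)
        return out

    def backward(self, grad):
        shape, idx = self._cache
        n, c, length = shape
        s = self.size
        lout = length // s
        dxr = np.zeros((n, c, lout, s), dtype=DTYPE)
        np.put_along_axis(dxr, idx[..., None], grad[..., None], axis=3)
        dx = np.zeros(shape, dtype=DTYPE)
        dx[:, :, : lout * s] = dxr.reshape(n, c, lout * s)
        return dx


class AdaptiveMaxPool1d(Layer):
    """Max pooling to a fixed output length with torch-style segment bounds."""

    def __init__(self, out_length: int):
        self.out_length = out_length

    @staticmethod
    def _bounds(length: int, out: int) -> list[tuple[int, int]]:
        return [(int(np.floor(i * length / out)), int(np.ceil((i + 1) * length / out)))
                for i in range(out)]

    def forward(self, x):
        n, c, length = x.shape
        bounds = self._bounds(length, self.out_length)
        out = np.empty((n, c, self.out_length), dtype=DTYPE)
        argmax = np.empty((n, c, self.out_length), dtype=np.int64)
        for i, (lo, hi) in enumerate(bounds):
            seg = x[:, :, lo:hi]
            a = seg.argmax(axis=2)
            argmax[:, :, i] = a + lo
            out[:, :, i] = np.take_along_axis(seg, a[..., None], axis=2)[..., 0]
        self._cache = (x.shape, argmax)
        return out

    def backward(self, grad):
        shape, argmax = self._cache
        dx = np.zeros(shape, dtype=DTYPE)
        n, c, _ = shape
        flat = (np.arange(n)[:, None, None] * c + np.arange(c)[None, :, None]) * shape[2] + argmax
        np.add.at(dx.reshape(-1), flat.ravel(), grad.ravel())
        return dx


class Dropout(Layer):
    """Inverted dropout; identity in eval mode. Needs an rng bound per step."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x):
        if not self.training or self.rate == 0.0:
            self._cache = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout used in training mode without an rng bound")
        keep = 1.0 - self.rate
        mask = (self.rng.random(x.shape, dtype=np.float32) < keep).astype(DTYPE) / keep
        self._cache = mask
        return x * mask

    def backward(self, grad):
        if self._cache is None:
            return grad
        return grad * self._cache


class Flatten(Layer):
    def forward(self, x):
        self._cache = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._cache)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, scale, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features))

    def parameters(self):
        return [self.weight, self.bias]

    def forward(self, x):
        x = np.asarray(x, dtype=DTYPE)
        self._cache = x
        return x @ self.weight.value + self.bias.value

    def backward(self, grad):
        x = self._cache
        self.weight.grad += x.T @ grad
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.value.T

    def state_dict(self):
        return {"weight": self.weight.value, "bias": self.bias.value}

    def load_state_dict(self, state):
        self.weight.value = np.ascontiguousarray(state["weight"], dtype=DTYPE)
        self.weight.grad = np.zeros_like(self.weight.value)
        self.bias.value = np.ascontiguousarray(state["bias"], dtype=DTYPE)
        self.bias.grad = np.zeros_like(self.bias.value)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def train(self):
        self.training = True
        for layer in self.layers:
            layer.train()

    def eval(self):
        self.training = False
        for layer in self.layers:
            layer.eval()

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def bind_dropout_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng
            elif isinstance(layer, Sequential):
                layer.bind_dropout_rng(rng)

    def state_dict(self):
        out = {}
        for i, layer in enumerate(self.layers):
            for key, val in layer.state_dict().items():
                out[f"{i}.{key}"] = val
        return out

    def load_state_dict(self, state):
        for i, layer in enumerate(self.layers):
            sub = {key.split(".", 1)[1]: val for key, val in state.items()
                   if key.split(".", 1)[0] == str(i)}
            if sub:
                layer.load_state_dict(sub)


class SGD:
    """SGD with classical momentum; skips frozen parameters."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self._velocity = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if not p.trainable:
                continue
            v *= self.momentum
            v -= self.lr * p.grad
            p.value += v


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy over the batch and its gradient w.r.t. the logits."""
    logits = np.asarray(logits, dtype=np.float64)
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    probs = ez / ez.sum(axis=1, keepdims=True)
    n = logits.shape[0]
    loss = -np.log(np.maximum(probs[np.arange(n), labels], 1e-300)).mean()
    grad = probs
    grad[np.arange(n), labels] -= 1.0
    return float(loss), (grad / n).astype(DTYPE)
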
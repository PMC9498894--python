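"""Sequence-activity regression networks.

Two architectures share one tail (activation -> joint strand pooling ->
dropout -> fully connected layers -> scalar):

* :func:`build_multinomial_cnn` -- a single convolution layer whose kernels
  are multinomial distributions derived from raw weights through a
  temperature softmax at every forward pass, scoring each window by its
  background-corrected log-likelihood ratio.
* :func:`build_conventional_cnn` -- a stack of ordinary (unconstrained)
  convolutions used as a baseline.

Both score the forward strand and the reverse complement with shared
weights and pool the two activated score vectors jointly, so predictions
are invariant under reverse complementation of the input.

The networks are implemented directly in NumPy with hand-written reverse-mode
gradients and an Adam optimizer; at the package's scale (a few hundred
filters, kilobase-free MPRA-length sequences) CPU NumPy is fast enough and
keeps the dependency footprint small.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (
    DEFAULT_BACKGROUND,
    BackgroundDistribution,
    RawConvolution,
    one_hot_encode,
    reverse_complement,
)
from .data import MPRADataset
from .exceptions import (
    ConfigError,
    DataError,
    DimensionError,
    DivergenceError,
)

__all__ = [
    "ConventionalConfig",
    "ModelConfig",
    "TrainedModel",
    "build_conventional_cnn",
    "build_multinomial_cnn",
    "encode_sequences",
    "load_model",
    "mse_loss",
    "predict",
    "save_model",
    "train",
]

_ACTIVATIONS = ("relu", "elu", "sigmoid", "tanh")
_POOLINGS = ("max", "sum", "average")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Hyperparameters of the multinomial-convolution network.

    Defaults reproduce the best cross-validated architecture: 512 filters of
    length 12, ReLU, max pooling, dropout 0.4, one dense node, L2 factor
    0.001, batch size 64, learning rate 0.001.  ``alpha`` defaults to 120,
    the midpoint of the searched 100-140 range; it is a fixed hyperparameter
    unless ``trainable_alpha`` is set.
    """

    n_filters: int = 512
    filter_length: int = 12
    alpha: float = 120.0
    trainable_alpha: bool = False
    activation: str = "relu"
    pooling: str = "max"
    dropout_rate: float = 0.4
    n_dense_layers: int = 1
    dense_hidden_units: int = 16
    l2_factor: float = 0.001
    batch_size: int = 64
    learning_rate: float = 0.001
    max_epochs: int = 100
    early_stopping_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_filters < 1:
            raise ConfigError(f"n_filters must be >= 1, got {self.n_filters}")
        if self.filter_length < 1:
            raise ConfigError(f"filter_length must be >= 1, got {self.filter_length}")
        if self.alpha <= 0:
            raise ConfigError(f"alpha must be positive, got {self.alpha}")
        if self.activation not in _ACTIVATIONS:
            raise ConfigError(
                f"activation must be one of {_ACTIVATIONS}, got {self.activation!r}"
            )
        if self.pooling not in _POOLINGS:
            raise ConfigError(
                f"pooling must be one of {_POOLINGS}, got {self.pooling!r}"
            )
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.n_dense_layers not in (1, 2):
            raise ConfigError(f"n_dense_layers must be 1 or 2, got {self.n_dense_layers}")
        if self.l2_factor < 0:
            raise ConfigError(f"l2_factor must be >= 0, got {self.l2_factor}")
        if self.batch_size < 1 or self.learning_rate <= 0:
            raise ConfigError("batch_size must be >= 1 and learning_rate positive")
        if self.max_epochs < 0 or self.early_stopping_patience < 0:
            raise ConfigError("epoch counts must be non-negative")

    def n_parameters(self) -> int:
        count = self.n_filters * self.filter_length * 4
        if self.n_dense_layers == 1:
            count += self.n_filters + 1
        else:
            count += (self.n_filters + 1) * self.dense_hidden_units
            count += self.dense_hidden_units + 1
        if self.trainable_alpha:
            count += 1
        return count


@dataclass
class ConventionalConfig:
    """Hyperparameters of the conventional-CNN baseline.

    Defaults reproduce the best baseline found by the same search: five
    convolution layers of 512/256/64/64/64 filters, all of length 5, ELU
    activation, max pooling, dropout 0.5, batch size 32.
    """

    filters_per_layer: tuple[int, ...] = (512, 256, 64, 64, 64)
    filter_length: int = 5
    activation: str = "elu"
    pooling: str = "max"
    dropout_rate: float = 0.5
    n_dense_layers: int = 1
    dense_hidden_units: int = 16
    l2_factor: float = 0.001
    batch_size: int = 32
    learning_rate: float = 0.001
    max_epochs: int = 100
    early_stopping_patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.filters_per_layer = tuple(int(f) for f in self.filters_per_layer)
        if len(self.filters_per_layer) < 1 or any(
            f < 1 for f in self.filters_per_layer
        ):
            raise ConfigError("filters_per_layer must be a non-empty tuple of counts")
        if self.filter_length < 1:
            raise ConfigError("filter_length must be >= 1")
        if self.activation not in ("relu", "elu", "sigmoid", "tanh"):
            raise ConfigError(f"unknown activation {self.activation!r}")
        if self.pooling not in _POOLINGS:
            raise ConfigError(f"unknown pooling {self.pooling!r}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigError("dropout_rate must be in [0, 1)")
        if self.n_dense_layers not in (1, 2):
            raise ConfigError("n_dense_layers must be 1 or 2")


# ---------------------------------------------------------------------------
# Layers (functional forward/backward with per-layer caches)
# ---------------------------------------------------------------------------


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class _Layer:
    """Base layer: named parameters plus forward/backward with caching."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.regularized: set[str] = set()
        self._cache = None

    def init(self, rng: np.random.Generator) -> None:  # pragma: no cover - trivial
        pass

    def forward(self, x, training: bool, rng: np.random.Generator | None):
        raise NotImplementedError

    def backward(self, grad):
        raise NotImplementedError


class _MultinomialConv(_Layer):
    """Convolution whose kernels are per-row softmax distributions.

    Parameters are the raw weights ``X`` of shape (filters, L, 4).  The
    forward pass re-derives the kernels from ``X`` every time so gradients
    flow through the softmax; the per-window score is the LLR against the
    background.  Output shape (batch, N - L + 1, filters).
    """

    def __init__(
        self,
        n_filters: int,
        filter_length: int,
        alpha: float,
        background: BackgroundDistribution,
        trainable_alpha: bool = False,
    ) -> None:
        super().__init__()
        self.n_filters = n_filters
        self.filter_length = filter_length
        self.background = background
        self.trainable_alpha = trainable_alpha
        self.params["X"] = np.zeros((n_filters, filter_length, 4))
        self.params["log_alpha"] = np.array([np.log(alpha)])
        self.regularized = {"X"}

    @property
    def alpha(self) -> float:
        return float(np.exp(self.params["log_alpha"][0]))

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.filter_length * 4
        fan_out = self.filter_length * self.n_filters
        x = _glorot_uniform(
            rng, (self.n_filters, self.filter_length, 4), fan_in, fan_out
        )
        # Scale by 1/alpha so initial kernels are near-uniform: at alpha ~ 120
        # an unscaled glorot draw saturates the softmax, producing hugely
        # negative LLRs that a ReLU zeroes out, killing all gradients.
        self.params["X"] = x / self.alpha

    def forward(self, x, training, rng=None):
        alpha = self.alpha
        scaled = alpha * self.params["X"]  # (F, L, 4)
        shifted = scaled - scaled.max(axis=2, keepdims=True)
        exp = np.exp(shifted)
        z = exp.sum(axis=2, keepdims=True)
        log_t = shifted - np.log(z)
        t = exp / z
        llr = log_t - self.background.log_probs[np.newaxis, np.newaxis, :]
        windows = np.lib.stride_tricks.sliding_window_view(
            x, self.filter_length, axis=1
        )  # (B, K, 4, L)
        out = np.einsum("bkjl,flj->bkf", windows, llr)
        self._cache = (windows, t, alpha, scaled)
        return out

    def backward(self, grad):
        windows, t, alpha, scaled = self._cache
        d_llr = np.einsum("bkf,bkjl->flj", grad, windows)
        # d log T[i, j] / d X[i, j'] = alpha * (delta_{jj'} - T[i, j'])
        row_tot = d_llr.sum(axis=2, keepdims=True)
        self.grads["X"] = alpha * (d_llr - t * row_tot)
        if self.trainable_alpha:
            # d log T / d alpha = X[i, j] - sum_j' T[i, j'] X[i, j']
            mean_x = (t * self.params["X"]).sum(axis=2, keepdims=True)
            d_alpha = float(np.sum(d_llr * (self.params["X"] - mean_x)))
            self.grads["log_alpha"] = np.array([d_alpha * alpha])
        else:
            self.grads["log_alpha"] = np.zeros(1)
        return None  # first layer: input gradient never needed

    def raw_convolutions(self) -> list[RawConvolution]:
        return [RawConvolution(w) for w in self.params["X"]]


class _Conv1D(_Layer):
    """Ordinary valid-mode 1-D convolution over the channel axis."""

    def __init__(self, filter_length: int, in_channels: int, out_channels: int,
                 first: bool = False) -> None:
        super().__init__()
        self.filter_length = filter_length
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.first = first
        self.params["kernel"] = np.zeros((filter_length, in_channels, out_channels))
        self.params["bias"] = np.zeros(out_channels)
        self.regularized = {"kernel"}

    def init(self, rng: np.random.Generator) -> None:
        fan_in = self.filter_length * self.in_channels
        fan_out = self.filter_length * self.out_channels
        self.params["kernel"] = _glorot_uniform(
            rng, self.params["kernel"].shape, fan_in, fan_out
        )
        self.params["bias"] = np.zeros(self.out_channels)

    def forward(self, x, training, rng=None):
        if x.shape[1] < self.filter_length:
            raise DimensionError(
                f"input length {x.shape[1]} shorter than filter length "
                f"{self.filter_length}"
            )
        windows = np.lib.stride_tricks.sliding_window_view(
            x, self.filter_length, axis=1
        )  # (B, K, C, L)
        out = np.einsum("bkcl,lco->bko", windows, self.params["kernel"])
        out += self.params["bias"]
        self._cache = windows
        return out

    def backward(self, grad):
        windows = self._cache
        self.grads["kernel"] = np.einsum("bko,bkcl->lco", grad, windows)
        self.grads["bias"] = grad.sum(axis=(0, 1))
        if self.first:
            return None
        pad = self.filter_length - 1
        padded = np.pad(grad, ((0, 0), (pad, pad), (0, 0)))
        gwin = np.lib.stride_tricks.sliding_window_view(
            padded, self.filter_length, axis=1
        )  # (B, N, O, L)
        return np.einsum("bnot,tco->bnc", gwin, self.params["kernel"][::-1])


class _Activation(_Layer):
    def __init__(self, name: str) -> None:
        super().__init__()
        self.name = name

    def forward(self, x, training, rng=None):
        if self.name == "relu":
            out = np.maximum(x, 0.0)
        elif self.name == "elu":
            out = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
        elif self.name == "sigmoid":
            out = 1.0 / (1.0 + np.exp(-x))
        elif self.name == "tanh":
            out = np.tanh(x)
        else:  # pragma: no cover - guarded by config validation
            raise ConfigError(f"unknown activation {self.name!r}")
        self._cache = (x, out)
        return out

    def backward(self, grad):
        x, out = self._cache
        if self.name == "relu":
            return grad * (x > 0)
        if self.name == "elu":
            return grad * np.where(x > 0, 1.0, out + 1.0)
        if self.name == "sigmoid":
            return grad * out * (1.0 - out)
        return grad * (1.0 - out * out)


class _GlobalPool(_Layer):
    """Pool over the position axis: (B, K, C) -> (B, C)."""

    def __init__(self, mode: str) -> None:
        super().__init__()
        self.mode = mode

    def forward(self, x, training, rng=None):
        if self.mode == "max":
            idx = x.argmax(axis=1)
            self._cache = (x.shape, idx)
            return np.take_along_axis(x, idx[:, np.newaxis, :], axis=1)[:, 0, :]
        if self.mode == "sum":
            self._cache = (x.shape, None)
            return x.sum(axis=1)
        self._cache = (x.shape, None)
        return x.mean(axis=1)

    def backward(self, grad):
        shape, idx = self._cache
        if self.mode == "max":
            out = np.zeros(shape)
            np.put_along_axis(out, idx[:, np.newaxis, :], grad[:, np.newaxis, :], axis=1)
            return out
        if self.mode == "sum":
            return np.broadcast_to(grad[:, np.newaxis, :], shape).copy()
        return np.broadcast_to(grad[:, np.newaxis, :] / shape[1], shape).copy()


class _Dropout(_Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        self.rate = rate

    def forward(self, x, training, rng=None):
        if not training or self.rate == 0.0:
            self._cache = None
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.shape) < keep) / keep
        self._cache = mask
        return x * mask

    def backward(self, grad):
        if self._cache is None:
            return grad
        return grad * self._cache


class _Dense(_Layer):
    def __init__(self, in_units: int, out_units: int) -> None:
        super().__init__()
        self.in_units = in_units
        self.out_units = out_units
        self.params["weight"] = np.zeros((in_units, out_units))
        self.params["bias"] = np.zeros(out_units)
        self.regularized = {"weight"}

    def init(self, rng: np.random.Generator) -> None:
        self.params["weight"] = _glorot_uniform(
            rng, (self.in_units, self.out_units), self.in_units, self.out_units
        )
        self.params["bias"] = np.zeros(self.out_units)

    def forward(self, x, training, rng=None):
        self._cache = x
        return x @ self.params["weight"] + self.params["bias"]

    def backward(self, grad):
        x = self._cache
        self.grads["weight"] = x.T @ grad
        self.grads["bias"] = grad.sum(axis=0)
        return grad @ self.params["weight"].T


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


class SequenceRegressor:
    """Shared-weight two-strand CNN regressor (untrained until :func:`train`).

    ``conv_layers`` run on both the forward and the reverse-complement
    encoding (stacked along the batch axis); the two resulting per-position
    score matrices are concatenated along the position axis and pooled
    jointly, which makes the prediction strand-symmetric by construction.
    """

    kind = "generic"

    def __init__(self, config, conv_layers, tail_layers) -> None:
        self.config = config
        self.conv_layers: list[_Layer] = conv_layers
        self.tail_layers: list[_Layer] = tail_layers
        self.input_length: int | None = None
        self.initialize(config.seed)

    # -- parameter plumbing -------------------------------------------------

    @property
    def layers(self) -> list[_Layer]:
        return self.conv_layers + self.tail_layers

    def initialize(self, seed: int) -> None:
        rng = np.random.default_rng(seed)
        for layer in self.layers:
            layer.init(rng)

    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name, value in layer.params.items():
                yield (li, name), layer, value

    def get_state(self) -> dict:
        return {
            f"layer{li}.{name}": value.copy()
            for (li, name), _, value in self.parameters()
        }

    def set_state(self, state: dict) -> None:
        for (li, name), layer, _ in self.parameters():
            layer.params[name] = np.array(state[f"layer{li}.{name}"], dtype=float)

    def l2_penalty(self, l2_factor: float) -> float:
        if l2_factor == 0.0:
            return 0.0
        total = 0.0
        for layer in self.layers:
            for name in layer.regularized:
                total += float(np.sum(layer.params[name] ** 2))
        return l2_factor * total

    # -- forward / backward -------------------------------------------------

    def forward(self, fwd, rc, training=False, rng=None):
        batch = fwd.shape[0]
        x = np.concatenate([fwd, rc], axis=0)
        for layer in self.conv_layers:
            x = layer.forward(x, training, rng)
        self._n_positions = x.shape[1]
        h = np.concatenate([x[:batch], x[batch:]], axis=1)  # (B, 2K, C)
        for layer in self.tail_layers:
            h = layer.forward(h, training, rng)
        return h[:, 0]

    def backward(self, grad_out) -> None:
        g = grad_out[:, np.newaxis]
        for layer in reversed(self.tail_layers):
            g = layer.backward(g)
        k = self._n_positions
        g = np.concatenate([g[:, :k], g[:, k:]], axis=0)
        for layer in reversed(self.conv_layers):
            g = layer.backward(g)

    # -- introspection ------------------------------------------------------

    def n_parameters(self) -> int:
        return sum(v.size for _, _, v in self.parameters())

    @property
    def dense_layers(self) -> list[_Dense]:
        return [l for l in self.tail_layers if isinstance(l, _Dense)]


class MultinomialNetwork(SequenceRegressor):
    kind = "multinomial"

    def __init__(self, config: ModelConfig,
                 background: BackgroundDistribution = DEFAULT_BACKGROUND) -> None:
        self.background = background
        conv = _MultinomialConv(
            config.n_filters,
            config.filter_length,
            config.alpha,
            background,
            trainable_alpha=config.trainable_alpha,
        )
        tail: list[_Layer] = [
            _Activation(config.activation),
            _GlobalPool(config.pooling),
            _Dropout(config.dropout_rate),
        ]
        if config.n_dense_layers == 1:
            tail.append(_Dense(config.n_filters, 1))
        else:
            tail.append(_Dense(config.n_filters, config.dense_hidden_units))
            tail.append(_Activation("relu"))
            tail.append(_Dense(config.dense_hidden_units, 1))
        super().__init__(config, [conv], tail)

    @property
    def conv(self) -> _MultinomialConv:
        return self.conv_layers[0]

    @property
    def alpha(self) -> float:
        return self.conv.alpha

    def raw_convolutions(self) -> list[RawConvolution]:
        return self.conv.raw_convolutions()

    def dense_weights(self) -> tuple[np.ndarray, float]:
        """Per-filter weight vector and intercept (single-dense-layer case)."""
        if self.config.n_dense_layers != 1:
            raise ConfigError(
                "per-filter dense weights are only defined for a single dense layer"
            )
        dense = self.dense_layers[0]
        return dense.params["weight"][:, 0].copy(), float(dense.params["bias"][0])


class ConventionalNetwork(SequenceRegressor):
    kind = "conventional"

    def __init__(self, config: ConventionalConfig) -> None:
        conv_layers: list[_Layer] = []
        in_channels = 4
        for depth, n_filters in enumerate(config.filters_per_layer):
            conv_layers.append(
                _Conv1D(config.filter_length, in_channels, n_filters, first=depth == 0)
            )
            conv_layers.append(_Activation(config.activation))
            in_channels = n_filters
        tail: list[_Layer] = [
            _GlobalPool(config.pooling),
            _Dropout(config.dropout_rate),
        ]
        if config.n_dense_layers == 1:
            tail.append(_Dense(in_channels, 1))
        else:
            tail.append(_Dense(in_channels, config.dense_hidden_units))
            tail.append(_Activation("relu"))
            tail.append(_Dense(config.dense_hidden_units, 1))
        super().__init__(config, conv_layers, tail)

    @property
    def n_conv_layers(self) -> int:
        return sum(isinstance(l, _Conv1D) for l in self.conv_layers)


def build_multinomial_cnn(
    config: ModelConfig | None = None,
    background: BackgroundDistribution = DEFAULT_BACKGROUND,
) -> MultinomialNetwork:
    """Build an untrained multinomial-convolution network."""
    return MultinomialNetwork(config or ModelConfig(), background)


def build_conventional_cnn(
    config: ConventionalConfig | None = None,
) -> ConventionalNetwork:
    """Build the untrained conventional-CNN baseline."""
    return ConventionalNetwork(config or ConventionalConfig())


# ---------------------------------------------------------------------------
# Loss, encoding, training, prediction
# ---------------------------------------------------------------------------


def mse_loss(y: Sequence[float], y_hat: Sequence[float]) -> float:
    """Mean squared error ``(1/n) * sum (y_i - yhat_i)^2``."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise DimensionError(f"shape mismatch: {y.shape} vs {y_hat.shape}")
    if y.size == 0:
        raise DataError("mse_loss requires n >= 1")
    return float(np.mean((y - y_hat) ** 2))


def encode_sequences(sequences: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """One-hot encode a batch; returns (forward, reverse_complement) arrays."""
    fwd = np.stack([one_hot_encode(s).matrix for s in sequences])
    rc = fwd[:, ::-1, ::-1].copy()
    return fwd, rc


class _Adam:
    def __init__(self, network: SequenceRegressor, learning_rate: float,
                 beta1=0.9, beta2=0.999, eps=1e-7) -> None:
        self.network = network
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {key: np.zeros_like(v) for key, _, v in network.parameters()}
        self.v = {key: np.zeros_like(v) for key, _, v in network.parameters()}

    def step(self, l2_factor: float) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for key, layer, value in self.network.parameters():
            name = key[1]
            grad = layer.grads.get(name)
            if grad is None:
                continue
            if l2_factor and name in layer.regularized:
                grad = grad + 2.0 * l2_factor * value
            m = self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * grad
            v = self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * grad**2
            layer.params[name] = value - self.lr * (m / b1t) / (
                np.sqrt(v / b2t) + self.eps
            )


@dataclass
class TrainedModel:
    """A fitted network plus its config and per-epoch loss history."""

    network: SequenceRegressor
    history: dict = field(default_factory=dict)

    @property
    def config(self):
        return self.network.config

    def predict(self, sequences: Sequence[str]) -> np.ndarray:
        return predict(self, sequences)

    @property
    def raw_convolutions(self):
        return self.network.raw_convolutions()

    def dense_weights(self):
        return self.network.dense_weights()


def _forward_eval(network: SequenceRegressor, fwd, rc, batch_size=512) -> np.ndarray:
    out = []
    for start in range(0, fwd.shape[0], batch_size):
        out.append(network.forward(fwd[start:start + batch_size],
                                   rc[start:start + batch_size], training=False))
    return np.concatenate(out)


def train(
    network: SequenceRegressor,
    data: MPRADataset,
    validation: MPRADataset | None = None,
) -> TrainedModel:
    """Fit with Adam on MSE + L2, early-stopping on validation MSE.

    Weights start from the network's glorot-uniform initialization (seeded by
    ``config.seed``).  With a validation set, training stops after
    ``early_stopping_patience`` epochs without improvement and the best
    weights are restored.  A zero ``max_epochs`` returns the initialization
    untouched.
    """
    config = network.config
    if len(data) == 0:
        raise DataError("training dataset is empty")
    if validation is not None and validation.sequence_length != data.sequence_length:
        raise DimensionError(
            "training and validation sequences must share one length"
        )
    fwd, rc = encode_sequences(data.sequences)
    y = data.activities
    if validation is not None:
        vfwd, vrc = encode_sequences(validation.sequences)
        vy = validation.activities
    network.input_length = data.sequence_length

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7EA1]))
    optimizer = _Adam(network, config.learning_rate)
    history: dict = {"train_loss": [], "val_loss": [], "best_epoch": None}
    best_val = np.inf
    best_state = None
    patience_left = config.early_stopping_patience
    n = len(data)

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            pred = network.forward(fwd[idx], rc[idx], training=True, rng=rng)
            residual = pred - y[idx]
            with np.errstate(over="ignore"):
                loss = float(np.mean(residual**2))
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            epoch_losses.append(loss)
            network.backward(2.0 * residual / idx.size)
            optimizer.step(config.l2_factor)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        if validation is not None:
            val_mse = mse_loss(vy, _forward_eval(network, vfwd, vrc))
            if not np.isfinite(val_mse):
                raise DivergenceError(epoch)
            history["val_loss"].append(val_mse)
            if val_mse < best_val - 1e-12:
                best_val = val_mse
                best_state = network.get_state()
                history["best_epoch"] = epoch
                patience_left = config.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left < 0:
                    break

    if best_state is not None:
        network.set_state(best_state)
    return TrainedModel(network=network, history=history)


def predict(model: TrainedModel | SequenceRegressor,
            sequences: Sequence[str]) -> np.ndarray:
    """Deterministic forward pass with dropout disabled."""
    network = model.network if isinstance(model, TrainedModel) else model
    lengths = {len(s) for s in sequences}
    if network.input_length is not None and lengths != {network.input_length}:
        raise DimensionError(
            f"sequence lengths {sorted(lengths)} do not match training length "
            f"{network.input_length}"
        )
    fwd, rc = encode_sequences(sequences)
    return _forward_eval(network, fwd, rc)


# ---------------------------------------------------------------------------
# Checkpointing (JSON: text-only, human-inspectable)
# ---------------------------------------------------------------------------

_CHECKPOINT_VERSION = 1


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize config + weights + history to a JSON checkpoint."""
    network = model.network
    config_dict = asdict(network.config)
    if "filters_per_layer" in config_dict:
        config_dict["filters_per_layer"] = list(config_dict["filters_per_layer"])
    payload = {
        "format_version": _CHECKPOINT_VERSION,
        "kind": network.kind,
        "config": config_dict,
        "input_length": network.input_length,
        "params": {k: v.tolist() for k, v in network.get_state().items()},
        "history": model.history,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TrainedModel:
    """Rebuild a network from a JSON checkpoint written by :func:`save_model`."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format_version") != _CHECKPOINT_VERSION:
        raise DataError(f"unsupported checkpoint version {payload.get('format_version')}")
    kind = payload["kind"]
    if kind == "multinomial":
        network: SequenceRegressor = MultinomialNetwork(ModelConfig(**payload["config"]))
    elif kind == "conventional":
        network = ConventionalNetwork(ConventionalConfig(**payload["config"]))
    else:
        raise DataError(f"unknown model kind {kind!r}")
    network.set_state({k: np.array(v, dtype=float) for k, v in payload["params"].items()})
    network.input_length = payload.get("input_length")
    return TrainedModel(network=network, history=payload.get("history", {}))
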
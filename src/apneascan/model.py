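"""The modified LeNet-5 1-D convolutional classifier.

The network maps a (900, 2) RR/amplitude window to a two-class softmax:

    input (900, 2)
    -> conv1d 32 filters, kernel 5, stride 2, no pad, relu   -> (448, 32)
    -> max-pool 3, stride 3                                  -> (149, 32)
    -> conv1d 64 filters, kernel 5, stride 2, no pad, relu   -> (73, 64)
    -> max-pool 3, stride 3                                  -> (24, 64)
    -> dropout, drop probability 0.8
    -> dense 32, relu
    -> dense 2, softmax

The architecture is held as data (:class:`ModelSpec`), so output-shape and
parameter-count arithmetic can be checked without instantiating a network.
Forward, backward and the Adam update are implemented directly on NumPy
arrays; training minimizes the categorical cross entropy by back-propagation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .ecg_io import APNEA, NORMAL
from .preprocess import WindowTensor

__all__ = [
    "LayerSpec",
    "ModelSpec",
    "TrainConfig",
    "PredictionSet",
    "modified_lenet5",
    "layer_output_length",
    "shape_trace",
    "count_parameters",
    "softmax",
    "cross_entropy_loss",
    "build_model",
    "train",
    "predict_proba",
]

# Class index convention used throughout: column 0 = normal, column 1 = apnea.
CLASS_ORDER = (NORMAL, APNEA)


@dataclass(frozen=True)
class LayerSpec:
    """One layer of the architecture, as declarative data."""

    kind: str  # conv1d | maxpool1d | dropout | dense | softmax_output
    filters: int | None = None
    units: int | None = None
    kernel: int | None = None
    stride: int = 1
    pad: int = 0
    rate: float | None = None
    activation: str = "none"

    def __post_init__(self) -> None:
        if self.kernel is not None and self.kernel < 1:
            raise ValueError("kernel must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.rate is not None and not 0 <= self.rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")


@dataclass(frozen=True)
class ModelSpec:
    """Full architecture: input geometry plus an ordered layer list."""

    input_length: int = 900
    input_channels: int = 2
    layers: tuple[LayerSpec, ...] = ()


def modified_lenet5(dropout_rate: float = 0.8) -> ModelSpec:
    """The published modified LeNet-5 for two-channel 900-point windows."""
    return ModelSpec(
        input_length=900,
        input_channels=2,
        layers=(
            LayerSpec(kind="conv1d", filters=32, kernel=5, stride=2, activation="relu"),
            LayerSpec(kind="maxpool1d", kernel=3, stride=3),
            LayerSpec(kind="conv1d", filters=64, kernel=5, stride=2, activation="relu"),
            LayerSpec(kind="maxpool1d", kernel=3, stride=3),
            LayerSpec(kind="dropout", rate=dropout_rate),
            LayerSpec(kind="dense", units=32, activation="relu"),
            LayerSpec(kind="softmax_output", units=2, activation="softmax"),
        ),
    )


def layer_output_length(l_in: int, kernel: int, stride: int, pad: int = 0) -> int:
    """Output length of a valid (un-padded unless ``pad``>0) sliding window.

    ``floor((l_in + 2*pad - kernel) / stride) + 1`` — for pooling layers the
    kernel is the pool size.
    """
    if l_in + 2 * pad < kernel:
        raise ValueError(f"input length {l_in} too small for kernel {kernel} (pad {pad})")
    return (l_in + 2 * pad - kernel) // stride + 1


def shape_trace(spec: ModelSpec) -> list[tuple[str, tuple[int, ...]]]:
    """Per-layer output shapes ``(length, channels)`` / ``(units,)``."""
    length, channels = spec.input_length, spec.input_channels
    flat: int | None = None
    trace: list[tuple[str, tuple[int, ...]]] = [("input", (length, channels))]
    for layer in spec.layers:
        if layer.kind in ("conv1d", "maxpool1d"):
            if flat is not None:
                raise ValueError(f"{layer.kind} after a dense layer")
            length = layer_output_length(length, layer.kernel, layer.stride, layer.pad)
            if layer.kind == "conv1d":
                channels = layer.filters
            trace.append((layer.kind, (length, channels)))
        elif layer.kind == "dropout":
            trace.append((layer.kind, trace[-1][1]))
        elif layer.kind in ("dense", "softmax_output"):
            flat = layer.units
            trace.append((layer.kind, (layer.units,)))
        else:
            raise ValueError(f"unknown layer kind {layer.kind!r}")
    return trace


def count_parameters(spec: ModelSpec) -> tuple[list[int], int]:
    """Trainable-parameter count per layer (weights + biases) and the total."""
    length, channels = spec.input_length, spec.input_channels
    fan_in: int | None = None
    counts: list[int] = []
    for layer in spec.layers:
        if layer.kind == "conv1d":
            counts.append(layer.filters * layer.kernel * channels + layer.filters)
            length = layer_output_length(length, layer.kernel, layer.stride, layer.pad)
            channels = layer.filters
        elif layer.kind == "maxpool1d":
            counts.append(0)
            length = layer_output_length(length, layer.kernel, layer.stride, layer.pad)
        elif layer.kind == "dropout":
            counts.append(0)
        elif layer.kind in ("dense", "softmax_output"):
            if fan_in is None:
                fan_in = length * channels
            counts.append(layer.units * fan_in + layer.units)
            fan_in = layer.units
        else:
            raise ValueError(f"unknown layer kind {layer.kind!r}")
    return counts, sum(counts)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax, computed with max-subtraction for stability."""
    z = np.asarray(z, dtype=float)
    shifted = z - z.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_loss(y_true: np.ndarray, y_pred: np.ndarray, eps: float = 1e-12) -> float:
    """Mean categorical cross entropy between one-hot rows and probabilities."""
    y_true = np.atleast_2d(np.asarray(y_true, dtype=float))
    y_pred = np.atleast_2d(np.asarray(y_pred, dtype=float))
    if y_true.shape != y_pred.shape:
        raise ValueError(f"shape mismatch {y_true.shape} vs {y_pred.shape}")
    return float(-np.mean(np.sum(y_true * np.log(np.clip(y_pred, eps, None)), axis=1)))


class _Conv1D:
    def __init__(self, in_channels: int, layer: LayerSpec, rng: np.random.Generator):
        self.kernel, self.stride = layer.kernel, layer.stride
        self.relu = layer.activation == "relu"
        fan_in = layer.kernel * in_channels
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), (layer.filters, in_channels, layer.kernel))
        self.b = np.zeros(layer.filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        win = sliding_window_view(x, self.kernel, axis=1)[:, :: self.stride]
        self._win, self._x_shape = win, x.shape
        z = np.tensordot(win, self.W, axes=([2, 3], [1, 2])) + self.b
        self._z = z
        return np.maximum(z, 0.0) if self.relu else z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = dout * (self._z > 0)
        self.dW = np.tensordot(dout, self._win, axes=([0, 1], [0, 1]))
        self.db = dout.sum(axis=(0, 1))
        batch, length, channels = self._x_shape
        dx = np.zeros((batch, length, channels))
        pos = self.stride * np.arange(dout.shape[1])
        for i in range(self.kernel):
            dx[:, pos + i, :] += dout @ self.W[:, :, i]
        return dx

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _MaxPool1D:
    def __init__(self, layer: LayerSpec):
        self.kernel, self.stride = layer.kernel, layer.stride
        if self.kernel != self.stride:
            raise ValueError("pooling implemented for kernel == stride")

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        batch, length, channels = x.shape
        l_out = layer_output_length(length, self.kernel, self.stride)
        x = x[:, : l_out * self.stride]
        blocks = x.reshape(batch, l_out, self.kernel, channels)
        self._arg = blocks.argmax(axis=2)
        self._in_shape = (batch, length, channels)
        return blocks.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        batch, length, channels = self._in_shape
        l_out = dout.shape[1]
        dx = np.zeros((batch, l_out, self.kernel, channels))
        b_idx, l_idx, c_idx = np.ogrid[:batch, :l_out, :channels]
        dx[b_idx, l_idx, self._arg, c_idx] = dout
        out = np.zeros((batch, length, channels))
        out[:, : l_out * self.stride] = dx.reshape(batch, l_out * self.kernel, channels)
        return out

    def params(self):
        return []


class _Dropout:
    def __init__(self, layer: LayerSpec):
        self.rate = layer.rate

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask

    def params(self):
        return []


class _Dense:
    def __init__(self, fan_in: int, layer: LayerSpec, rng: np.random.Generator):
        self.relu = layer.activation == "relu"
        # the softmax head starts near-uniform (small init) so the initial
        # loss of a balanced problem sits at ln K
        std = 0.01 if layer.activation == "softmax" else np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, std, (fan_in, layer.units))
        self.b = np.zeros(layer.units)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        self._x = x
        z = x @ self.W + self.b
        self._z = z
        return np.maximum(z, 0.0) if self.relu else z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = dout * (self._z > 0)
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class LeNet1D:
    """A trainable instance of a :class:`ModelSpec`, with seeded init."""

    def __init__(self, spec: ModelSpec, seed: int = 0):
        shape_trace(spec)  # validates geometry end to end
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers = []
        length, channels = spec.input_length, spec.input_channels
        flat: int | None = None
        for layer in spec.layers:
            if layer.kind == "conv1d":
                layers.append(_Conv1D(channels, layer, rng))
                length = layer_output_length(length, layer.kernel, layer.stride, layer.pad)
                channels = layer.filters
            elif layer.kind == "maxpool1d":
                layers.append(_MaxPool1D(layer))
                length = layer_output_length(length, layer.kernel, layer.stride, layer.pad)
            elif layer.kind == "dropout":
                layers.append(_Dropout(layer))
            elif layer.kind in ("dense", "softmax_output"):
                if flat is None:
                    flat = length * channels
                layers.append(_Dense(flat, layer, rng))
                flat = layer.units
        self.layers = layers

    @property
    def n_parameters(self) -> int:
        return sum(p.size for lay in self.layers for p, _ in lay.params())

    def forward(self, x: np.ndarray, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        """Map (batch, 900, 2) windows to (batch, 2) class probabilities."""
        self._pre_flat_shape = None
        for lay in self.layers:
            if isinstance(lay, _Dense) and self._pre_flat_shape is None:
                self._pre_flat_shape = x.shape
                x = x.reshape(x.shape[0], -1)
            x = lay.forward(x, train, rng)
        self._logits = x
        return softmax(x)

    def backward(self, dlogits: np.ndarray) -> None:
        """Back-propagate a gradient w.r.t. the output logits."""
        dout = dlogits
        first_dense = next(
            i for i, lay in enumerate(self.layers) if isinstance(lay, _Dense)
        )
        for i in reversed(range(len(self.layers))):
            dout = self.layers[i].backward(dout)
            if i == first_dense:
                dout = dout.reshape(self._pre_flat_shape)
        return None

    def params(self):
        return [pg for lay in self.layers for pg in lay.params()]

    def state(self) -> list[np.ndarray]:
        return [p.copy() for lay in self.layers for p, _ in lay.params()]

    def load_state(self, state: Sequence[np.ndarray]) -> None:
        for (p, _), s in zip(self.params(), state):
            p[...] = s


@dataclass
class TrainConfig:
    """Training hyperparameters (seeded, CPU, Adam by back-propagation)."""

    learning_rate: float = 1e-3
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 10
    val_fraction: float = 0.1
    seed: int = 0
    class_weight: bool = False

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("learning_rate, batch_size and max_epochs must be positive")
        if not 0 <= self.val_fraction < 1:
            raise ValueError("val_fraction must be in [0, 1)")


@dataclass
class PredictionSet:
    """Per-window apnea probabilities and thresholded hard labels."""

    proba_apnea: np.ndarray
    threshold: float = 0.5

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(APNEA if p >= self.threshold else NORMAL for p in self.proba_apnea)


def build_model(spec: ModelSpec, seed: int = 0) -> LeNet1D:
    """Instantiate a seeded, trainable network from an architecture spec."""
    return LeNet1D(spec, seed=seed)


def windows_to_arrays(windows: Sequence[WindowTensor]) -> tuple[np.ndarray, np.ndarray]:
    """Stack window tensors into (N, L, 2) inputs and one-hot (N, 2) targets."""
    x = np.stack([w.channels for w in windows])
    y = np.zeros((len(windows), 2))
    for i, w in enumerate(windows):
        y[i, CLASS_ORDER.index(w.label)] = 1.0
    return x, y


class _Adam:
    def __init__(self, model: "LeNet1D", lr: float):
        self.model = model
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p, _ in model.params()]
        self.v = [np.zeros_like(p) for p, _ in model.params()]
        self.t = 0

    def step(self) -> None:
        # params() is re-queried: layers rebind their gradient arrays on
        # every backward pass.
        self.t += 1
        for i, (p, g) in enumerate(self.model.params()):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            m_hat = self.m[i] / (1 - self.beta1**self.t)
            v_hat = self.v[i] / (1 - self.beta2**self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(
    model: LeNet1D,
    windows: Sequence[WindowTensor],
    cfg: TrainConfig | None = None,
) -> tuple[LeNet1D, list[float]]:
    """Fit the network on labeled windows by minimizing cross entropy.

    Returns the model (trained in place, restored to its best validation
    state when early stopping is active) and the loss history; entry 0 is the
    pre-training loss of the initialized network on the training split.
    Requires both classes in the training data.
    """
    cfg = cfg or TrainConfig()
    x, y = windows_to_arrays(windows)
    if len(np.unique(y.argmax(axis=1))) < 2:
        raise ValueError("training set must contain both classes")
    rng = np.random.default_rng(cfg.seed)

    n = x.shape[0]
    order = rng.permutation(n)
    n_val = int(round(cfg.val_fraction * n))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    x_tr, y_tr = x[tr_idx], y[tr_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    weights = np.ones(2)
    if cfg.class_weight:
        counts = y_tr.sum(axis=0)
        weights = counts.sum() / (2.0 * np.maximum(counts, 1.0))

    opt = _Adam(model, cfg.learning_rate)
    history = [cross_entropy_loss(y_tr, model.forward(x_tr))]
    best_val = np.inf
    best_state = model.state()
    stall = 0
    for _ in range(cfg.max_epochs):
        perm = rng.permutation(len(tr_idx))
        for start in range(0, len(perm), cfg.batch_size):
            batch = perm[start : start + cfg.batch_size]
            xb, yb = x_tr[batch], y_tr[batch]
            proba = model.forward(xb, train=True, rng=rng)
            row_w = (yb * weights).sum(axis=1, keepdims=True)
            model.backward((proba - yb) * row_w / len(batch))
            opt.step()
        history.append(cross_entropy_loss(y_tr, model.forward(x_tr)))
        if n_val:
            val_loss = cross_entropy_loss(y_val, model.forward(x_val))
            if val_loss < best_val - 1e-6:
                best_val, best_state, stall = val_loss, model.state(), 0
            else:
                stall += 1
                if stall >= cfg.patience:
                    break
    if n_val:
        model.load_state(best_state)
    return model, history


def predict_proba(model: LeNet1D, windows: Sequence[WindowTensor], batch_size: int = 256) -> PredictionSet:
    """Apnea probability per window; dropout inactive (inference mode)."""
    if len(windows) == 0:
        return PredictionSet(proba_apnea=np.empty(0))
    x = np.stack([w.channels for w in windows])
    out = [
        model.forward(x[i : i + batch_size])[:, CLASS_ORDER.index(APNEA)]
        for i in range(0, x.shape[0], batch_size)
    ]
    return PredictionSet(proba_apnea=np.concatenate(out))
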
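"""The convolutional classifier and its analytic accounting.

Fixed architecture operating on 28x28x3 RGB digit images::

    conv 32@3x3 -> maxpool 2x2 -> conv 64@3x3 -> maxpool 2x2 -> conv 64@3x3
    -> flatten -> dense 64 -> dense 10 (softmax)

All convolutions are unpadded ("valid"), stride 1; pools are 2x2 stride 2
with floor on odd sizes.  Hidden nonlinearities are rectified-linear; the
output layer is a softmax over the 10 digit classes.  Per-layer trainable
parameter counts are 896 / 18,496 / 36,928 / 36,928 / 650 (93,898 total) and
output shapes run (26,26,32) -> (13,13,32) -> (11,11,64) -> (5,5,64) ->
(3,3,64) -> 576 -> 64 -> 10.

Training minimizes categorical cross-entropy on one-hot labels with the
RMSprop optimizer (the canonical compilation for this stack).  The forward
and backward passes are implemented directly in numpy via im2col matrix
multiplication, which keeps every run bit-reproducible for a given seed —
there is no framework nondeterminism to document.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import N_CLASSES, ColorDataset


class TrainingDivergenceError(RuntimeError):
    """The training loss became non-finite."""


# ---------------------------------------------------------------------------
# Declarative architecture and analytic accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LayerSpec:
    kind: str  # "conv" | "maxpool" | "flatten" | "dense"
    filters: int | None = None       # conv output depth
    units: int | None = None         # dense width
    kernel: tuple[int, int] | None = None  # conv (3,3) or pool (2,2)
    activation: str | None = None    # "relu" | "softmax" | None

    def __post_init__(self) -> None:
        if self.kind not in ("conv", "maxpool", "flatten", "dense"):
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind == "conv" and (self.filters is None or self.kernel is None):
            raise ValueError("conv layers need filters and kernel")
        if self.kind == "dense" and self.units is None:
            raise ValueError("dense layers need units")


@dataclass(frozen=True)
class NetworkSpec:
    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int, int] = (28, 28, 3)

    def output_shapes(self) -> list[tuple[int, ...] | int]:
        """Per-layer output shapes, in layer order."""
        shapes: list[tuple[int, ...] | int] = []
        shape: tuple[int, ...] | int = self.input_shape
        for layer in self.layers:
            shape = output_shape(layer, shape)
            shapes.append(shape)
        return shapes

    def parameter_counts(self) -> list[int]:
        """Trainable parameter counts of the conv/dense layers, in order."""
        counts = []
        shape: tuple[int, ...] | int = self.input_shape
        for layer in self.layers:
            if layer.kind == "conv":
                counts.append(count_parameters(layer, shape[2]))
            elif layer.kind == "dense":
                counts.append(count_parameters(layer, int(np.prod(shape))))
            shape = output_shape(layer, shape)
        return counts

    def total_parameters(self) -> int:
        return sum(self.parameter_counts())


def default_network_spec() -> NetworkSpec:
    """The fixed digit-classification architecture described above."""
    return NetworkSpec(
        layers=(
            LayerSpec("conv", filters=32, kernel=(3, 3), activation="relu"),
            LayerSpec("maxpool", kernel=(2, 2)),
            LayerSpec("conv", filters=64, kernel=(3, 3), activation="relu"),
            LayerSpec("maxpool", kernel=(2, 2)),
            LayerSpec("conv", filters=64, kernel=(3, 3), activation="relu"),
            LayerSpec("flatten"),
            LayerSpec("dense", units=64, activation="relu"),
            LayerSpec("dense", units=N_CLASSES, activation="softmax"),
        )
    )


def count_parameters(layer: LayerSpec, input_size: int) -> int:
    """Trainable parameters of one layer.

    For conv layers ``input_size`` is the input depth:
    ``(kh*kw*depth + 1) * filters``.  For dense layers it is the flat input
    width: ``(inputs + 1) * units``.  Pooling/flatten layers have none.
    """
    if layer.kind == "conv":
        kh, kw = layer.kernel
        return (kh * kw * input_size + 1) * layer.filters
    if layer.kind == "dense":
        return (input_size + 1) * layer.units
    return 0


def output_shape(
    layer: LayerSpec, input_shape: tuple[int, ...] | int
) -> tuple[int, ...] | int:
    """Shape produced by one layer from the given input shape.

    Valid convolution: (h-kh+1, w-kw+1, filters); pooling floors odd sizes.
    """
    if layer.kind == "conv":
        h, w, _ = input_shape
        kh, kw = layer.kernel
        if kh > h or kw > w:
            raise ValueError(f"kernel {layer.kernel} larger than input {input_shape}")
        return (h - kh + 1, w - kw + 1, layer.filters)
    if layer.kind == "maxpool":
        h, w, d = input_shape
        kh, kw = layer.kernel
        return (h // kh, w // kw, d)
    if layer.kind == "flatten":
        return int(np.prod(input_shape))
    # dense
    return layer.units


# ---------------------------------------------------------------------------
# Layer implementations (im2col numpy forward/backward)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(n,h,w,d) -> (n,oh,ow,kh*kw*d) view-copy of all valid 3x3 patches."""
    n, h, w, d = x.shape
    oh, ow = h - kh + 1, w - kw + 1
    s = x.strides
    patches = np.lib.stride_tricks.as_strided(
        x, (n, oh, ow, kh, kw, d), (s[0], s[1], s[2], s[1], s[2], s[3])
    )
    return patches.reshape(n, oh, ow, kh * kw * d)


class _Conv:
    def __init__(self, in_depth: int, filters: int, kernel: tuple[int, int],
                 rng: np.random.Generator):
        kh, kw = kernel
        fan_in, fan_out = kh * kw * in_depth, kh * kw * filters
        limit = np.sqrt(6.0 / (fan_in + fan_out))  # Glorot uniform
        self.W = rng.uniform(-limit, limit, size=(kh * kw * in_depth, filters))
        self.b = np.zeros(filters)
        self.kernel = kernel
        self.in_depth = in_depth

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        cols = _im2col(np.ascontiguousarray(x), *self.kernel)
        z = cols @ self.W + self.b
        y = np.maximum(z, 0.0)
        if train:
            self._cols, self._mask, self._in_shape = cols, z > 0.0, x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dz = dy * self._mask
        n, oh, ow, f = dz.shape
        kh, kw = self.kernel
        k = self.W.shape[0]
        self.dW = self._cols.reshape(-1, k).T @ dz.reshape(-1, f)
        self.db = dz.sum(axis=(0, 1, 2))
        dcols = (dz @ self.W.T).reshape(n, oh, ow, kh, kw, self.in_depth)
        dx = np.zeros(self._in_shape)
        for i in range(kh):
            for j in range(kw):
                dx[:, i:i + oh, j:j + ow, :] += dcols[:, :, :, i, j, :]
        return dx

    params = property(lambda self: [self.W, self.b])
    grads = property(lambda self: [self.dW, self.db])


class _MaxPool:
    def __init__(self, kernel: tuple[int, int]):
        self.kernel = kernel

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, d = x.shape
        kh, kw = self.kernel
        oh, ow = h // kh, w // kw
        blocks = (
            x[:, : oh * kh, : ow * kw, :]
            .reshape(n, oh, kh, ow, kw, d)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, oh, ow, kh * kw, d)
        )
        idx = blocks.argmax(axis=3)
        y = np.take_along_axis(blocks, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if train:
            self._idx, self._in_shape = idx, x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, d = self._in_shape
        kh, kw = self.kernel
        oh, ow = h // kh, w // kw
        dblocks = np.zeros((n, oh, ow, kh * kw, d))
        np.put_along_axis(dblocks, self._idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dx = np.zeros(self._in_shape)
        dx[:, : oh * kh, : ow * kw, :] = (
            dblocks.reshape(n, oh, ow, kh, kw, d)
            .transpose(0, 1, 3, 2, 4, 5)
            .reshape(n, oh * kh, ow * kw, d)
        )
        return dx

    params = property(lambda self: [])
    grads = property(lambda self: [])


class _Flatten:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._in_shape)

    params = property(lambda self: [])
    grads = property(lambda self: [])


class _Dense:
    def __init__(self, in_width: int, units: int, activation: str,
                 rng: np.random.Generator):
        limit = np.sqrt(6.0 / (in_width + units))
        self.W = rng.uniform(-limit, limit, size=(in_width, units))
        self.b = np.zeros(units)
        self.activation = activation

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        z = x @ self.W + self.b
        if self.activation == "relu":
            y = np.maximum(z, 0.0)
        else:  # softmax output; gradient handled jointly with the loss
            z = z - z.max(axis=1, keepdims=True)
            e = np.exp(z)
            y = e / e.sum(axis=1, keepdims=True)
        if train:
            self._x = x
            self._mask = (z > 0.0) if self.activation == "relu" else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        # For the softmax layer, dy must already be d(loss)/d(logits).
        dz = dy * self._mask if self._mask is not None else dy
        self.dW = self._x.T @ dz
        self.db = dz.sum(axis=0)
        return dz @ self.W.T

    params = property(lambda self: [self.W, self.b])
    grads = property(lambda self: [self.dW, self.db])


# ---------------------------------------------------------------------------
# Training configuration, the network object, training and evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingConfig:
    """Compilation + fit settings; loss/optimizer/metric are fixed choices."""

    loss: str = "categorical_crossentropy"
    optimizer: str = "rmsprop"
    metric: str = "accuracy"
    epochs: int = 5
    batch_size: int = 64
    learning_rate: float = 1e-3
    rho: float = 0.9
    epsilon: float = 1e-7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.loss != "categorical_crossentropy":
            raise ValueError("only categorical cross-entropy is supported")
        if self.optimizer != "rmsprop":
            raise ValueError("only the rmsprop optimizer is supported")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


class TrainedNetwork:
    """A built (and, after :func:`train`, fitted) instance of a NetworkSpec.

    Exposes class-probability prediction and per-layer intermediate
    activations.  ``conv_layer_positions`` maps the 1-based convolutional
    layer index used throughout the analysis to the position in the layer
    stack.
    """

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        self.seed = seed
        self.history: pd.DataFrame | None = None
        rng = np.random.default_rng(seed)
        self._layers = []
        shape: tuple[int, ...] | int = spec.input_shape
        for ls in spec.layers:
            if ls.kind == "conv":
                self._layers.append(_Conv(shape[2], ls.filters, ls.kernel, rng))
            elif ls.kind == "maxpool":
                self._layers.append(_MaxPool(ls.kernel))
            elif ls.kind == "flatten":
                self._layers.append(_Flatten())
            else:
                self._layers.append(_Dense(int(np.prod(shape)), ls.units, ls.activation, rng))
            shape = output_shape(ls, shape)
        self.conv_layer_positions = [
            i for i, ls in enumerate(spec.layers) if ls.kind == "conv"
        ]

    # -- accounting against the actual weight arrays --------------------
    def actual_parameter_counts(self) -> list[int]:
        """Parameter counts read off the instantiated weight arrays."""
        return [
            sum(p.size for p in layer.params)
            for layer in self._layers
            if layer.params
        ]

    # -- inference -------------------------------------------------------
    def _forward(self, x: np.ndarray, train: bool = False,
                 capture: int | None = None) -> np.ndarray:
        out = x
        for i, layer in enumerate(self._layers):
            out = layer.forward(out, train=train)
            if capture is not None and i == capture:
                return out
        return out

    def predict_proba(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """(n, 10) class probabilities, computed in batches."""
        outs = [
            self._forward(images[i:i + batch_size])
            for i in range(0, images.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)

    def layer_activations(self, images: np.ndarray, layer_index: int,
                          batch_size: int = 256) -> np.ndarray:
        """Post-relu output of convolutional layer ``layer_index`` (1-based)."""
        if not 1 <= layer_index <= len(self.conv_layer_positions):
            raise ValueError(
                f"layer_index must be in 1..{len(self.conv_layer_positions)}"
            )
        pos = self.conv_layer_positions[layer_index - 1]
        outs = [
            self._forward(images[i:i + batch_size], capture=pos)
            for i in range(0, images.shape[0], batch_size)
        ]
        return np.concatenate(outs, axis=0)


def train(
    spec: NetworkSpec, train_set: ColorDataset, config: TrainingConfig
) -> TrainedNetwork:
    """Fit the network on a colorized dataset.

    Minimizes categorical cross-entropy with RMSprop on shuffled mini
    batches; records per-epoch mean loss and training accuracy in
    ``network.history``.  Fully deterministic given ``config.seed``.

    Raises
    ------
    TrainingDivergenceError
        If the loss becomes non-finite.
    """
    net = TrainedNetwork(spec, seed=config.seed)
    rng = np.random.default_rng(config.seed + 1)
    x_all = train_set.images
    y_all = train_set.one_hot_labels()
    n = len(train_set)

    caches = [[np.zeros_like(p) for p in layer.params] for layer in net._layers]
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = x_all[idx], y_all[idx]
            probs = net._forward(xb, train=True)
            batch_loss = -np.mean(np.sum(yb * np.log(probs + 1e-12), axis=1))
            if not np.isfinite(batch_loss):
                raise TrainingDivergenceError(
                    f"non-finite loss at epoch {epoch + 1}"
                )
            losses.append(batch_loss)
            correct += int((probs.argmax(axis=1) == yb.argmax(axis=1)).sum())

            grad = (probs - yb) / xb.shape[0]  # d(loss)/d(logits)
            for layer in reversed(net._layers):
                grad = layer.backward(grad)
            for layer, cache in zip(net._layers, caches):
                for p, g, c in zip(layer.params, layer.grads, cache):
                    c *= config.rho
                    c += (1.0 - config.rho) * g * g
                    p -= config.learning_rate * g / (np.sqrt(c) + config.epsilon)
        history.append(
            {"epoch": epoch + 1, "loss": float(np.mean(losses)), "accuracy": correct / n}
        )
    net.history = pd.DataFrame(history)
    return net


@dataclass(frozen=True)
class EvaluationResult:
    """Test accuracy and row-normalized 10x10 confusion matrix."""

    accuracy: float
    confusion: np.ndarray  # rows: true label, cols: predicted; rows sum to 1

    def __post_init__(self) -> None:
        if self.confusion.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("confusion matrix must be 10x10")


def evaluate(network, test_set: ColorDataset) -> EvaluationResult:
    """Evaluate argmax predictions on a colorized test set.

    Ties in the probability vector break toward the lowest class index.
    Confusion rows are normalized by true-class counts; a class absent from
    the test set leaves an all-zero row.
    """
    if len(test_set) == 0:
        raise ValueError("empty test set")
    probs = network.predict_proba(test_set.images)
    pred = probs.argmax(axis=1)
    true = test_set.labels
    counts = np.zeros((N_CLASSES, N_CLASSES))
    np.add.at(counts, (true, pred), 1.0)
    row_sums = counts.sum(axis=1, keepdims=True)
    confusion = np.divide(counts, row_sums, out=np.zeros_like(counts),
                          where=row_sums > 0)
    return EvaluationResult(float((pred == true).mean()), confusion)
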
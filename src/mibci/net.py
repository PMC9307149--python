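"""The deep-learning decoding arm: a compact 2-D CNN on raw epochs.

Architecture: conv(30 filters, 5x5, valid) -> ReLU -> maxpool(2x2, floor)
-> flatten -> dense(256, ReLU) -> dense(128, ReLU) -> dense(2) -> softmax,
trained with Adam (lr 0.01) on categorical cross-entropy, full-batch when
the batch size exceeds the training-fold size.

Each epoch enters as a one-image-channel 2-D array (electrodes x samples).
Layers are implemented directly in numpy with analytic backward passes
(im2col convolution, argmax-routed pooling), so every gradient is checkable
against finite differences.  float32 is used for training speed; float64 is
available for verification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import evaluate
from .records import EvalResult
from .simulate import EpochSet

__all__ = [
    "relu", "softmax", "categorical_cross_entropy", "conv2d_forward",
    "CNNSpec", "TrainConfig", "DLConfig", "TrainingHistory", "Sequential",
    "build_model", "train", "run_dl_pipeline", "DivergenceError",
]


class DivergenceError(RuntimeError):
    """Training produced a non-finite loss; carries the last finite history."""

    def __init__(self, message: str, history: "TrainingHistory"):
        super().__init__(message)
        self.history = history


# ---------------------------------------------------------------------------
# functional primitives


def relu(x):
    """Rectified linear unit max(0, x), elementwise."""
    return np.maximum(0, x)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Stable softmax: exp(z - max) normalized along ``axis``."""
    z = np.asarray(z, dtype=float)
    shifted = z - z.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def categorical_cross_entropy(probs: np.ndarray, one_hot: np.ndarray,
                              clip: float = 1e-12) -> float:
    """Mean of -log p(true class) over the batch, with probability clipping."""
    probs = np.asarray(probs, dtype=float)
    one_hot = np.asarray(one_hot, dtype=float)
    if probs.shape != one_hot.shape:
        raise ValueError(f"shape mismatch {probs.shape} vs {one_hot.shape}")
    p_true = np.sum(np.clip(probs, clip, 1.0) * one_hot, axis=-1)
    return float(np.mean(-np.log(p_true)))


def conv2d_forward(image: np.ndarray, kernels: np.ndarray,
                   biases: np.ndarray) -> np.ndarray:
    """Valid cross-correlation of (N, C, H, W) inputs with (F, C, kh, kw) kernels.

    Cross-correlation (no kernel flip) follows deep-learning convention.
    """
    image = np.asarray(image)
    kernels = np.asarray(kernels)
    n, c, h, w = image.shape
    f, ck, kh, kw = kernels.shape
    if ck != c:
        raise ValueError(f"kernel channels {ck} != input channels {c}")
    if kh > h or kw > w:
        raise ValueError(f"kernel {kh}x{kw} larger than input {h}x{w}")
    view = np.lib.stride_tricks.sliding_window_view(image, (kh, kw), axis=(2, 3))
    # view: (N, C, OH, OW, kh, kw)
    out = np.einsum("nchwij,fcij->nfhw", view, kernels, optimize=True)
    return out + biases[None, :, None, None]


def _one_hot(labels: Sequence[int], n_classes: int = 2) -> np.ndarray:
    labels = np.asarray(labels)
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


# ---------------------------------------------------------------------------
# layers


class Layer:
    params: List[np.ndarray] = []
    grads: List[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """Valid cross-correlation layer; im2col + GEMM forward and backward."""

    def __init__(self, n_filters: int, kernel: Tuple[int, int], in_channels: int,
                 rng: np.random.Generator, dtype=np.float32):
        kh, kw = kernel
        # Glorot uniform (fan_avg), the default of the frameworks this
        # architecture is normally built in
        fan_in = in_channels * kh * kw
        fan_out = n_filters * kh * kw
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        self.kernels = rng.uniform(-limit, limit,
                                   size=(n_filters, in_channels, kh, kw)).astype(dtype)
        self.biases = np.zeros(n_filters, dtype=dtype)
        self.params = [self.kernels, self.biases]
        self.grads = [np.zeros_like(self.kernels), np.zeros_like(self.biases)]
        self.kernel = kernel

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        kh, kw = self.kernel
        n, c, h, w = x.shape
        if kh > h or kw > w:
            raise ValueError(f"Conv2D: kernel {kh}x{kw} larger than input {h}x{w}")
        oh, ow = h - kh + 1, w - kw + 1
        view = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
        cols = np.ascontiguousarray(view.transpose(0, 2, 3, 1, 4, 5)
                                    ).reshape(n * oh * ow, c * kh * kw)
        wmat = self.kernels.reshape(self.kernels.shape[0], -1)
        out = (cols @ wmat.T).reshape(n, oh, ow, -1).transpose(0, 3, 1, 2)
        if training:
            self._cache = (cols, x.shape)
        return np.ascontiguousarray(out) + self.biases[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n, c, h, w = x_shape
        f = self.kernels.shape[0]
        kh, kw = self.kernel
        oh, ow = h - kh + 1, w - kw + 1
        gmat = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(n * oh * ow, f)
        self.grads[0][...] = (gmat.T @ cols).reshape(self.kernels.shape)
        self.grads[1][...] = grad.sum(axis=(0, 2, 3))
        dcols = (gmat @ self.kernels.reshape(f, -1)).reshape(n, oh, ow, c, kh, kw)
        dx = np.zeros(x_shape, dtype=grad.dtype)
        for i in range(kh):
            for j in range(kw):
                dx[:, :, i:i + oh, j:j + ow] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dx


class ReLU(Layer):
    params: List[np.ndarray] = []
    grads: List[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            self._mask = x > 0
        return np.maximum(0, x)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool2D(Layer):
    """2x2 max pooling with floor semantics (trailing odd row/column dropped).

    The backward pass routes the gradient to every element equal to the
    window maximum; with continuous-valued inputs exact ties have measure
    zero, so in practice exactly one element per window receives it.
    """

    params: List[np.ndarray] = []
    grads: List[np.ndarray] = []

    def __init__(self, pool: Tuple[int, int] = (2, 2)):
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        ph, pw = self.pool
        n, f, h, w = x.shape
        oh, ow = h // ph, w // pw
        if oh == 0 or ow == 0:
            raise ValueError(f"MaxPool2D: input {h}x{w} smaller than pool {ph}x{pw}")
        # two single-axis reductions (much faster than one strided 2-axis max)
        xc = x[:, :, :oh * ph, :ow * pw]
        a = xc.reshape(n, f, oh * ph, ow, pw).max(axis=-1)  # columns first
        out = a.reshape(n, f, oh, ph, ow).max(axis=3)       # then rows
        if training:
            self._cache = (xc, a, out, x.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xc, a, out, x_shape = self._cache
        ph, pw = self.pool
        n, f, h, w = x_shape
        oh, ow = h // ph, w // pw
        # undo the row max, then the column max, via equality masks
        da = (a.reshape(n, f, oh, ph, ow) == out[:, :, :, None, :]) \
            * grad[:, :, :, None, :]
        da = da.reshape(n, f, oh * ph, ow)
        dx = np.zeros(x_shape, dtype=grad.dtype)
        dx[:, :, :oh * ph, :ow * pw] = (
            (xc.reshape(n, f, oh * ph, ow, pw) == a[..., None]) * da[..., None]
        ).reshape(n, f, oh * ph, ow * pw)
        return dx


class Flatten(Layer):
    params: List[np.ndarray] = []
    grads: List[np.ndarray] = []

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32, zero_init: bool = False):
        limit = np.sqrt(6.0 / (n_in + n_out))
        if zero_init:
            # zero-started output layer: logits begin at 0, which keeps the
            # first large-step Adam updates from slamming the ReLU stack
            self.W = np.zeros((n_in, n_out), dtype=dtype)
        else:
            self.W = rng.uniform(-limit, limit, size=(n_in, n_out)).astype(dtype)
        self.b = np.zeros(n_out, dtype=dtype)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ grad
        self.grads[1][...] = grad.sum(axis=0)
        return grad @ self.W.T


class Sequential:
    """A layer stack ending in logits; softmax applied at prediction time."""

    def __init__(self, layers: List[Layer]):
        self.layers = layers

    @property
    def params(self) -> List[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> List[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, training=False))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(x, training=False), axis=-1)

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))


# ---------------------------------------------------------------------------
# specs and configs


@dataclass(frozen=True)
class CNNSpec:
    """Layer plan of the compact 2-D CNN."""

    conv_filters: int = 30
    kernel: Tuple[int, int] = (5, 5)
    pool: Tuple[int, int] = (2, 2)
    dense_units: Tuple[int, ...] = (256, 128)
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.n_classes != 2:
            raise ValueError("binary task: n_classes must be 2")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam, categorical cross-entropy)."""

    learning_rate: float = 0.01
    batch_size: int = 264
    max_epochs: int = 500
    seed: int = 0
    normalize: bool = True  # per-channel z-scoring with train-fold statistics
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class TrainingHistory:
    loss: List[float] = field(default_factory=list)
    train_accuracy: List[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loss)


@dataclass(frozen=True)
class DLConfig:
    """End-to-end CNN pipeline settings."""

    spec: CNNSpec = CNNSpec()
    train: TrainConfig = TrainConfig()
    train_fraction: float = 0.8
    split_seed: int = 0


def build_model(spec: CNNSpec, input_shape: Tuple[int, int, int],
                seed: int = 0, dtype=np.float32) -> Sequential:
    """Assemble the seeded-initialized layer stack for (C, H, W) inputs.

    Weights use uniform fan-in (He-style) scaling, biases start at zero.
    Raises a shape error naming the offending layer when the kernel or pool
    does not fit.
    """
    c, h, w = input_shape
    kh, kw = spec.kernel
    if kh > h or kw > w:
        raise ValueError(f"conv layer: kernel {kh}x{kw} does not fit input {h}x{w}")
    oh, ow = h - kh + 1, w - kw + 1
    ph, pw = spec.pool
    if oh // ph == 0 or ow // pw == 0:
        raise ValueError(f"maxpool layer: feature map {oh}x{ow} smaller than pool")
    rng = np.random.default_rng(seed)
    layers: List[Layer] = [
        Conv2D(spec.conv_filters, spec.kernel, c, rng, dtype=dtype),
        ReLU(),
        MaxPool2D(spec.pool),
        Flatten(),
    ]
    n_in = spec.conv_filters * (oh // ph) * (ow // pw)
    for units in spec.dense_units:
        layers.append(Dense(n_in, units, rng, dtype=dtype))
        layers.append(ReLU())
        n_in = units
    layers.append(Dense(n_in, spec.n_classes, rng, dtype=dtype, zero_init=True))
    return Sequential(layers)


class Adam:
    """Canonical Adam with bias-corrected first and second moments."""

    def __init__(self, params: List[np.ndarray], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self._buf = [np.empty_like(p) for p in params]
        self.t = 0

    def step(self, grads: List[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1, c2 = 1 - b1 ** self.t, 1 - b2 ** self.t
        for p, g, m, v, buf in zip(self.params, grads, self.m, self.v, self._buf):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * (g * g)
            # p -= lr * (m/c1) / (sqrt(v/c2) + eps), computed in one buffer
            np.divide(v, c2, out=buf)
            np.sqrt(buf, out=buf)
            buf += self.eps
            np.divide(m, buf, out=buf)
            buf *= self.lr / c1
            p -= buf


def softmax_cce_grad(logits: np.ndarray, one_hot: np.ndarray
                     ) -> Tuple[float, np.ndarray]:
    """Loss and logit gradient of softmax + categorical cross-entropy."""
    p = softmax(logits)
    loss = categorical_cross_entropy(p, one_hot)
    grad = (p - one_hot) / logits.shape[0]
    return loss, grad.astype(logits.dtype)


def train(model: Sequential, X: np.ndarray, labels: Sequence[int],
          config: TrainConfig = TrainConfig()) -> TrainingHistory:
    """Mini-batch (or full-batch) Adam on categorical cross-entropy.

    Deterministic given ``config.seed`` (controls the per-epoch shuffles;
    initialization is seeded in :func:`build_model`).  When the batch size
    reaches the training-set size each epoch is a single full-batch step.
    Aborts with :class:`DivergenceError` on a non-finite loss.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    y = _one_hot(labels).astype(X.dtype)
    n = X.shape[0]
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params, config.learning_rate, config.beta1, config.beta2,
               config.eps)
    history = TrainingHistory()
    full_batch = config.batch_size >= n
    for _ in range(config.max_epochs):
        order = np.arange(n) if full_batch else rng.permutation(n)
        epoch_loss = 0.0
        n_correct = 0
        for start in range(0, n, config.batch_size):
            sel = order[start:start + config.batch_size]
            logits = model.forward(X[sel], training=True)
            loss, grad = softmax_cce_grad(logits, y[sel])
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite loss after {len(history)} epochs", history)
            model.backward(grad)
            opt.step(model.grads)
            epoch_loss += loss * len(sel)
            n_correct += int(np.sum(np.argmax(logits, axis=-1) == labels[sel]))
        history.loss.append(epoch_loss / n)
        history.train_accuracy.append(100.0 * n_correct / n)
    return history


def epochs_to_images(epochs: EpochSet, dtype=np.float32) -> np.ndarray:
    """(trials, channels, samples) -> (trials, 1, channels, samples)."""
    return np.ascontiguousarray(epochs.data[:, None, :, :], dtype=dtype)


def run_dl_pipeline(epochs: EpochSet, config: DLConfig = DLConfig()) -> EvalResult:
    """Raw epochs -> CNN, with the 80/20 split shared with the ML arm.

    Optional per-channel z-scoring uses statistics of the training fold only
    (no leakage); at microvolt scale, unnormalized inputs stall ReLU training.
    """
    train_idx, test_idx = evaluate.train_test_split(
        epochs.n_trials, epochs.labels, config.train_fraction, config.split_seed)
    X = epochs_to_images(epochs)
    y = epochs.labels
    X_train, X_test = X[train_idx], X[test_idx]
    if config.train.normalize:
        mean = X_train.mean(axis=(0, 3), keepdims=True)
        sd = X_train.std(axis=(0, 3), keepdims=True)
        sd[sd == 0] = 1.0
        X_train = (X_train - mean) / sd
        X_test = (X_test - mean) / sd
    model = build_model(config.spec, X.shape[1:], seed=config.train.seed,
                        dtype=X.dtype.type)
    train(model, X_train, y[train_idx], config.train)
    pred_train = model.predict(X_train)
    pred_test = model.predict(X_test)
    f_left, f_right = evaluate.f_score_per_class(pred_test, y[test_idx])
    return EvalResult(
        model_tag="CNN",
        train_accuracy=evaluate.accuracy(pred_train, y[train_idx]),
        test_accuracy=evaluate.accuracy(pred_test, y[test_idx]),
        f_score_left=f_left, f_score_right=f_right,
        split_seed=config.split_seed,
    )
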
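"""Tile classification: CNN primitives, a transfer-learned softmax head,
and a tiny built-in convolutional backbone.

The classifier follows the transfer-learning recipe used for Ki67 tumor /
non-tumor tiles: a pretrained network serves purely as a feature extractor
(the backbone, an injected contract), and only a softmax head — a single
dense layer followed by softmax — is trained on the two-class tile dataset,
by mini-batch stochastic gradient descent with momentum on label-smoothed
cross-entropy.  A ``full_finetune`` mode additionally backpropagates into
the built-in backbone's convolution kernels, mirroring the fine-tune-
everything baseline.

The numeric primitives (valid cross-correlation, ReLU, max pooling, dense
layer, softmax, label smoothing, the cross-entropy that averages over the
``M`` classes, SGD with momentum, exponential decay) are authored here
explicitly; they are the computation of record and each is checked against
an independent oracle in the test suite.

Class order is fixed throughout the package: index 0 = tumor,
index 1 = non_tumor.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "CLASSES",
    "ClassProbabilities",
    "SoftmaxHead",
    "TrainingConfig",
    "TinyBackbone",
    "TileClassifier",
    "conv2d_xcorr",
    "relu",
    "max_pool",
    "dense_forward",
    "softmax",
    "smooth_labels",
    "cross_entropy",
    "sgd_momentum_step",
    "apply_exponential_decay",
    "head_loss_and_grad",
    "train_head",
    "train_full_finetune",
    "predict_tile",
    "save_model",
    "load_model",
]

#: fixed class order: column 0 of every probability array is tumor
CLASSES = ("tumor", "non_tumor")


# ---------------------------------------------------------------------------
# primitives


def conv2d_xcorr(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Valid 2-D cross-correlation of ``image`` with ``kernel``.

    Output entry (q, r) is ``sum_{m,n} I(q+m, r+n) * K(m, n)``; the output
    size is ``(H - kh + 1, W - kw + 1)``.
    """
    image = np.asarray(image, dtype=float)
    kernel = np.asarray(kernel, dtype=float)
    if image.ndim != 2 or kernel.ndim != 2:
        raise ValueError("image and kernel must be 2-D")
    if kernel.shape[0] > image.shape[0] or kernel.shape[1] > image.shape[1]:
        raise ValueError("kernel larger than image")
    windows = sliding_window_view(image, kernel.shape)
    return np.einsum("qrmn,mn->qr", windows, kernel)


def relu(x: np.ndarray) -> np.ndarray:
    """Elementwise max(0, x)."""
    return np.maximum(np.asarray(x), 0)


def max_pool(x: np.ndarray, window: int, stride: int) -> np.ndarray:
    """Max pooling of a 2-D array over a ``window`` x ``window`` grid."""
    x = np.asarray(x, dtype=float)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if x.ndim != 2:
        raise ValueError("input must be 2-D")
    if window > min(x.shape):
        raise ValueError("window larger than input")
    windows = sliding_window_view(x, (window, window))[::stride, ::stride]
    return windows.max(axis=(-2, -1))


def dense_forward(x: np.ndarray, weights: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Fully-connected layer: ``y_j = sum_i w_ij x_i + b_j``.

    Accepts a single feature vector ``(d,)`` or a batch ``(n, d)``; the
    activation, if any, is applied by the caller.
    """
    x = np.asarray(x, dtype=float)
    weights = np.asarray(weights, dtype=float)
    bias = np.asarray(bias, dtype=float)
    if x.shape[-1] != weights.shape[0] or weights.shape[1] != bias.shape[0]:
        raise ValueError(
            f"dimension mismatch: x {x.shape}, W {weights.shape}, b {bias.shape}"
        )
    return x @ weights + bias


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax: ``p_k = exp(z_k) / sum_j exp(z_j)``.

    The maximum is subtracted before exponentiation, which leaves the result
    unchanged and prevents overflow.
    """
    z = np.asarray(z, dtype=float)
    shifted = z - z.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def smooth_labels(one_hot: np.ndarray, eps: float, k: int | None = None) -> np.ndarray:
    """Label smoothing: 0s become ``eps/k``; the 1 becomes ``1 - eps*(k-1)/k``.

    ``eps`` is interpreted as the estimated proportion of mislabeled
    training samples.  The smoothed vector still sums to one.
    """
    t = np.asarray(one_hot, dtype=float)
    if not 0 <= eps < 1:
        raise ValueError("eps must be in [0, 1)")
    if k is None:
        k = t.shape[-1]
    elif k != t.shape[-1]:
        raise ValueError("k does not match vector length")
    is01 = np.all((t == 0) | (t == 1))
    if not is01 or not np.all(t.sum(axis=-1) == 1):
        raise ValueError("input must be one-hot indicator vectors")
    return np.where(t == 1, 1.0 - eps * (k - 1) / k, eps / k)


def cross_entropy(target: np.ndarray, predicted: np.ndarray, m: int | None = None) -> float:
    """Cross-entropy loss ``L = -(1/M) * sum_j target_j * log(predicted_j)``.

    Averages over the ``M`` classes (not the batch dimension); for a batch
    (2-D inputs) the result is the mean of the per-sample losses.  Predicted
    probabilities of exactly zero where the target is positive are clamped
    at 1e-12 with a warning.
    """
    t = np.atleast_2d(np.asarray(target, dtype=float))
    p = np.atleast_2d(np.asarray(predicted, dtype=float))
    if t.shape != p.shape:
        raise ValueError("target and predicted shapes differ")
    if m is None:
        m = t.shape[-1]
    elif m != t.shape[-1]:
        raise ValueError("M does not match vector length")
    if np.any((p == 0) & (t > 0)):
        warnings.warn("predicted probability 0 at a positive target; clamped at 1e-12",
                      stacklevel=2)
    p = np.clip(p, 1e-12, None)
    per_sample = -(t * np.log(p)).sum(axis=-1) / m
    return float(per_sample.mean())


def sgd_momentum_step(params, grads, velocity, lr: float, momentum: float):
    """One SGD-with-momentum update.

    ``velocity' = momentum * velocity + grads``;
    ``params'   = params - lr * velocity'``.
    Accepts single arrays or lists of arrays (updated in parallel).
    Returns ``(params', velocity')``.
    """
    single = isinstance(params, np.ndarray)
    ps = [params] if single else list(params)
    gs = [grads] if single else list(grads)
    vs = [velocity] if single else list(velocity)
    new_v = [momentum * v + g for v, g in zip(vs, gs)]
    new_p = [p - lr * v for p, v in zip(ps, new_v)]
    if single:
        return new_p[0], new_v[0]
    return new_p, new_v


def apply_exponential_decay(value: float, factor: float, epoch: int) -> float:
    """Exponential schedule: ``value * factor**epoch``."""
    if not 0 < factor <= 1:
        raise ValueError("factor must be in (0, 1]")
    return value * factor ** epoch


# ---------------------------------------------------------------------------
# model containers


@dataclass
class ClassProbabilities:
    """Two-class softmax output for a single tile."""

    p_tumor: float
    p_non_tumor: float

    def __post_init__(self) -> None:
        if self.p_tumor < 0 or self.p_non_tumor < 0:
            raise ValueError("probabilities must be non-negative")
        if abs(self.p_tumor + self.p_non_tumor - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p_tumor, self.p_non_tumor])


@dataclass
class SoftmaxHead:
    """The trained classifier head: a ``d x M`` dense layer + softmax.

    ``feature_mean`` / ``feature_scale``, when set, z-score incoming
    features with statistics frozen from the training split — the head's
    own input normalization, stored with the model so training and
    inference see identical inputs.
    """

    weights: np.ndarray  # (d, M)
    bias: np.ndarray  # (M,)
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.feature_mean is not None:
            self.feature_mean = np.asarray(self.feature_mean, dtype=float)
            self.feature_scale = np.asarray(self.feature_scale, dtype=float)
        if self.weights.ndim != 2 or self.bias.ndim != 1:
            raise ValueError("weights must be 2-D, bias 1-D")
        if self.weights.shape[1] != self.bias.shape[0]:
            raise ValueError("weights/bias class dimensions differ")
        if self.weights.shape[1] < 2:
            raise ValueError("need at least 2 classes")
        if not (np.all(np.isfinite(self.weights)) and np.all(np.isfinite(self.bias))):
            raise ValueError("parameters must be finite")

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]

    @property
    def n_classes(self) -> int:
        return self.weights.shape[1]

    def normalize(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if self.feature_mean is None:
            return x
        return (x - self.feature_mean) / self.feature_scale

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Softmax class probabilities for a feature batch ``(n, d)``."""
        return softmax(dense_forward(self.normalize(features), self.weights, self.bias))


@dataclass
class TrainingConfig:
    """Optimizer hyperparameters for head training and fine-tuning.

    Defaults follow the transfer recipe: learning rate 0.01, momentum 0.9,
    mini-batch 100 over 3000 iterations, 10% of the training data held out
    for validation, label smoothing eps 0.1.  The head recipe states no
    schedule, so both exponential decays default to 1.0 (constant);
    ``full_finetune`` (the fine-tune-everything baseline) conventionally
    uses lr 1e-4 with per-epoch decay 0.9, momentum decay 0.9, batch 128,
    10 epochs.
    """

    learning_rate: float = 0.01
    lr_exp_decay: float = 1.0
    momentum: float = 0.9
    momentum_decay: float = 1.0
    batch_size: int = 100
    iterations: int = 3000
    epochs: int = 10
    validation_fraction: float = 0.1
    label_smoothing_eps: float = 0.1
    mode: str = "head_only"
    seed: int = 0
    eval_interval: int = 100

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if not 0 <= self.label_smoothing_eps < 1:
            raise ValueError("label_smoothing_eps must be in [0, 1)")
        if self.mode not in ("head_only", "full_finetune"):
            raise ValueError("mode must be head_only or full_finetune")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# head training


def _encode_labels(labels) -> np.ndarray:
    """Map labels (class names or {0,1} ints) to class indices."""
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        if isinstance(lab, str):
            try:
                out[i] = CLASSES.index(lab)
            except ValueError:
                raise ValueError(f"unknown label {lab!r}") from None
        else:
            out[i] = int(lab)
    if not np.isin(out, (0, 1)).all():
        raise ValueError("labels must be tumor/non_tumor (0/1)")
    return out


def head_loss_and_grad(
    weights: np.ndarray,
    bias: np.ndarray,
    features: np.ndarray,
    targets: np.ndarray,
):
    """Smoothed-cross-entropy loss of a softmax head and its analytic gradient.

    ``targets`` are (already smoothed) target rows summing to one.  Because
    the loss averages over the ``M`` classes and over the ``B`` batch rows,
    the gradient with respect to the logits is ``(p - t) / (M * B)``.
    Returns ``(loss, dW, db)``.
    """
    x = np.atleast_2d(features)
    t = np.atleast_2d(targets)
    p = softmax(dense_forward(x, weights, bias))
    m = t.shape[1]
    b = t.shape[0]
    loss = cross_entropy(t, p, m)
    dz = (p - t) / (m * b)
    return loss, x.T @ dz, dz.sum(axis=0)


def _accuracy(head: SoftmaxHead, features: np.ndarray, y: np.ndarray) -> float:
    return float((head.predict_proba(features).argmax(axis=1) == y).mean())


def _validation_split(n: int, fraction: float, rng: np.random.Generator):
    perm = rng.permutation(n)
    n_val = max(1, int(round(fraction * n)))
    if n_val >= n:
        raise ValueError("validation split leaves no training data")
    return perm[n_val:], perm[:n_val]


def train_head(
    features: np.ndarray,
    labels,
    config: TrainingConfig | None = None,
) -> tuple[SoftmaxHead, pd.DataFrame]:
    """Train the softmax head on frozen backbone features.

    A seeded ``validation_fraction`` split is held out; the head (zero-
    initialized — the problem is convex) is optimized by mini-batch SGD with
    momentum on label-smoothed cross-entropy, with per-epoch exponential
    decay of both the learning rate and the momentum coefficient.  One epoch
    is one pass over the shuffled training split; ``iterations`` counts
    mini-batch steps.

    Returns the trained head and a history frame with training/validation
    loss and accuracy sampled every ``eval_interval`` iterations.
    """
    config = config or TrainingConfig()
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValueError("features must be (n, d)")
    if not np.all(np.isfinite(x)):
        raise ValueError("features must be finite")
    y = _encode_labels(labels)
    if len(y) != len(x):
        raise ValueError("features and labels length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")

    rng = np.random.default_rng(config.seed)
    train_idx, val_idx = _validation_split(len(x), config.validation_fraction, rng)
    if len(np.unique(y[train_idx])) < 2:
        raise ValueError("validation split left a single-class training set")
    x_train, y_train = x[train_idx], y[train_idx]
    x_val, y_val = x[val_idx], y[val_idx]

    # freeze feature z-scoring on the training split; constant features
    # get scale 1 so they stay constant instead of dividing by zero
    feat_mean = x_train.mean(axis=0)
    feat_scale = x_train.std(axis=0)
    feat_scale[feat_scale == 0] = 1.0
    x_train = (x_train - feat_mean) / feat_scale
    x_val = (x_val - feat_mean) / feat_scale

    m = 2
    one_hot = np.eye(m)[y_train]
    targets = smooth_labels(one_hot, config.label_smoothing_eps, m)

    w = np.zeros((x.shape[1], m))
    b = np.zeros(m)
    v = [np.zeros_like(w), np.zeros_like(b)]
    n_train = len(x_train)
    steps_per_epoch = max(1, int(np.ceil(n_train / config.batch_size)))
    history: list[dict] = []
    perm = rng.permutation(n_train)

    for it in range(config.iterations):
        epoch = it // steps_per_epoch
        step_in_epoch = it % steps_per_epoch
        if step_in_epoch == 0 and it > 0:
            perm = rng.permutation(n_train)
        lr = apply_exponential_decay(config.learning_rate, config.lr_exp_decay, epoch)
        mom = apply_exponential_decay(config.momentum, config.momentum_decay, epoch)
        sl = perm[step_in_epoch * config.batch_size : (step_in_epoch + 1) * config.batch_size]
        loss, dw, db = head_loss_and_grad(w, b, x_train[sl], targets[sl])
        (w, b), v = sgd_momentum_step([w, b], [dw, db], v, lr, mom)
        if (it + 1) % config.eval_interval == 0 or it == config.iterations - 1:
            head = SoftmaxHead(weights=w, bias=b)
            train_loss, _, _ = head_loss_and_grad(w, b, x_train, targets)
            val_loss = cross_entropy(np.eye(m)[y_val], head.predict_proba(x_val), m)
            history.append(
                {
                    "iteration": it + 1,
                    "epoch": epoch,
                    "learning_rate": lr,
                    "train_loss": train_loss,
                    "train_accuracy": _accuracy(head, x_train, y_train),
                    "val_loss": val_loss,
                    "val_accuracy": _accuracy(head, x_val, y_val),
                }
            )
    return (
        SoftmaxHead(weights=w, bias=b, feature_mean=feat_mean, feature_scale=feat_scale),
        pd.DataFrame(history),
    )


# ---------------------------------------------------------------------------
# built-in backbone


def _pool2_forward(a: np.ndarray):
    """2x2 stride-2 max pool of (n, H, W, C) with an argmax cache.

    Odd trailing rows/columns are dropped (floor behavior).
    """
    n, h, w, c = a.shape
    h2, w2 = h // 2, w // 2
    r = (
        a[:, : h2 * 2, : w2 * 2]
        .reshape(n, h2, 2, w2, 2, c)
        .transpose(0, 1, 3, 5, 2, 4)
        .reshape(n, h2, w2, c, 4)
    )
    idx = r.argmax(axis=-1)
    pooled = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
    return pooled, idx


def _pool2_backward(grad: np.ndarray, idx: np.ndarray, in_shape) -> np.ndarray:
    n, h, w, c = in_shape
    h2, w2 = h // 2, w // 2
    r = np.zeros((n, h2, w2, c, 4))
    np.put_along_axis(r, idx[..., None], grad[..., None], axis=-1)
    out = np.zeros(in_shape)
    out[:, : h2 * 2, : w2 * 2] = (
        r.reshape(n, h2, w2, c, 2, 2)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(n, h2 * 2, w2 * 2, c)
    )
    return out


def _conv_forward(x: np.ndarray, kernels: np.ndarray, bias: np.ndarray) -> np.ndarray:
    """Valid multi-channel cross-correlation of (n,H,W,Cin) with (Cout,Cin,k,k)."""
    k = kernels.shape[-1]
    windows = sliding_window_view(x, (k, k), axis=(1, 2))  # (n, H', W', Cin, k, k)
    return np.einsum("nhwcij,ocij->nhwo", windows, kernels, optimize=True) + bias


def _conv_backward(x: np.ndarray, kernels: np.ndarray, dz: np.ndarray):
    """Gradients of a valid multi-channel cross-correlation.

    Returns ``(dK, db, dX)`` for input ``x`` (n,H,W,Cin), kernels
    (Cout,Cin,k,k) and upstream gradient ``dz`` (n,H',W',Cout).
    """
    k = kernels.shape[-1]
    windows = sliding_window_view(x, (k, k), axis=(1, 2))
    dk = np.einsum("nhwcij,nhwo->ocij", windows, dz, optimize=True)
    db = dz.sum(axis=(0, 1, 2))
    dx = np.zeros_like(x)
    hp, wp = dz.shape[1], dz.shape[2]
    for i in range(k):
        for j in range(k):
            dx[:, i : i + hp, j : j + wp, :] += np.einsum(
                "nhwo,oc->nhwc", dz, kernels[:, :, i, j], optimize=True
            )
    return dk, db, dx


@dataclass
class TinyBackbone:
    """A small fixed convolutional feature extractor for desk-scale runs.

    Two conv-ReLU-maxpool blocks followed by global average pooling, with
    seeded random kernels (He-style scale).  It satisfies the feature-
    extractor contract — deterministic ``embed`` with a constant feature
    length — and is the backbone the tests and the demo pipeline use.  In
    ``full_finetune`` mode its kernels are trainable.
    """

    channels1: int = 8
    channels2: int = 16
    kernel_size: int = 5
    seed: int = 0
    trainable: bool = False
    name: str = "tiny"

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        k = self.kernel_size
        self.kernels1 = rng.normal(0.0, np.sqrt(2.0 / (3 * k * k)), (self.channels1, 3, k, k))
        self.bias1 = np.zeros(self.channels1)
        self.kernels2 = rng.normal(
            0.0, np.sqrt(2.0 / (self.channels1 * k * k)), (self.channels2, self.channels1, k, k)
        )
        self.bias2 = np.zeros(self.channels2)

    @property
    def n_features(self) -> int:
        return self.channels2

    @staticmethod
    def _as_float_batch(tiles: np.ndarray) -> np.ndarray:
        x = np.asarray(tiles, dtype=float)
        if x.ndim == 3:
            x = x[None]
        if x.ndim != 4 or x.shape[-1] != 3:
            raise ValueError("tiles must be (n, H, W, 3) or (H, W, 3)")
        return x / 255.0

    def _forward(self, x: np.ndarray):
        z1 = _conv_forward(x, self.kernels1, self.bias1)
        a1 = relu(z1)
        p1, idx1 = _pool2_forward(a1)
        z2 = _conv_forward(p1, self.kernels2, self.bias2)
        a2 = relu(z2)
        p2, idx2 = _pool2_forward(a2)
        feats = p2.mean(axis=(1, 2))
        cache = {"x": x, "z1": z1, "a1": a1, "idx1": idx1, "p1": p1,
                 "z2": z2, "a2": a2, "idx2": idx2, "p2_shape": p2.shape}
        return feats, cache

    def embed_batch(self, tiles: np.ndarray) -> np.ndarray:
        """Feature vectors (n, d) for a batch of RGB tiles."""
        feats, _ = self._forward(self._as_float_batch(tiles))
        return feats

    def embed(self, tile: np.ndarray) -> np.ndarray:
        """Feature vector (d,) for a single RGB tile."""
        return self.embed_batch(tile)[0]

    def _backward(self, cache: dict, dfeats: np.ndarray):
        """Gradients of the kernels/biases given d(loss)/d(features)."""
        n, hp, wp, c2 = cache["p2_shape"]
        dp2 = np.broadcast_to(dfeats[:, None, None, :] / (hp * wp), (n, hp, wp, c2))
        da2 = _pool2_backward(dp2, cache["idx2"], cache["a2"].shape)
        dz2 = da2 * (cache["z2"] > 0)
        dk2, db2, dp1 = _conv_backward(cache["p1"], self.kernels2, dz2)
        da1 = _pool2_backward(dp1, cache["idx1"], cache["a1"].shape)
        dz1 = da1 * (cache["z1"] > 0)
        dk1, db1, _ = _conv_backward(cache["x"], self.kernels1, dz1)
        return dk1, db1, dk2, db2

    def parameters(self) -> list[np.ndarray]:
        return [self.kernels1, self.bias1, self.kernels2, self.bias2]

    def set_parameters(self, params) -> None:
        self.kernels1, self.bias1, self.kernels2, self.bias2 = [
            np.asarray(p, dtype=float) for p in params
        ]


def train_full_finetune(
    tiles: np.ndarray,
    labels,
    config: TrainingConfig | None = None,
    backbone: TinyBackbone | None = None,
) -> tuple["TileClassifier", pd.DataFrame]:
    """Fine-tune the built-in backbone and the head jointly.

    The fine-tune-everything baseline: the loss gradient backpropagates
    through both conv blocks, and all parameters are updated with SGD
    momentum under the per-epoch exponential decays of ``config``.  Runs
    ``config.epochs`` passes over the shuffled training split with
    ``config.batch_size`` mini-batches.
    """
    config = config or TrainingConfig(
        mode="full_finetune", learning_rate=1e-4, lr_exp_decay=0.9, batch_size=128
    )
    backbone = backbone or TinyBackbone(seed=config.seed)
    backbone.trainable = True
    x = TinyBackbone._as_float_batch(np.asarray(tiles))
    y = _encode_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")

    rng = np.random.default_rng(config.seed)
    train_idx, val_idx = _validation_split(len(x), config.validation_fraction, rng)
    x_train, y_train = x[train_idx], y[train_idx]
    x_val, y_val = x[val_idx], y[val_idx]
    m = 2
    targets = smooth_labels(np.eye(m)[y_train], config.label_smoothing_eps, m)

    w = np.zeros((backbone.n_features, m))
    b = np.zeros(m)
    params = backbone.parameters() + [w, b]
    velocity = [np.zeros_like(p) for p in params]
    n_train = len(x_train)
    history: list[dict] = []

    for epoch in range(config.epochs):
        lr = apply_exponential_decay(config.learning_rate, config.lr_exp_decay, epoch)
        mom = apply_exponential_decay(config.momentum, config.momentum_decay, epoch)
        perm = rng.permutation(n_train)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n_train, config.batch_size):
            sl = perm[start : start + config.batch_size]
            feats, cache = backbone._forward(x_train[sl])
            loss, dw, db = head_loss_and_grad(w, b, feats, targets[sl])
            p = softmax(dense_forward(feats, w, b))
            dz = (p - targets[sl]) / (m * len(sl))
            dfeats = dz @ w.T
            dk1, db1, dk2, db2 = backbone._backward(cache, dfeats)
            grads = [dk1, db1, dk2, db2, dw, db]
            params, velocity = sgd_momentum_step(params, grads, velocity, lr, mom)
            backbone.set_parameters(params[:4])
            w, b = params[4], params[5]
            epoch_loss += loss
            n_batches += 1
        head = SoftmaxHead(weights=w, bias=b)
        clf = TileClassifier(backbone=backbone, head=head)
        val_acc = float(
            (clf.predict_proba_features(backbone.embed_batch(x_val * 255.0)).argmax(1) == y_val).mean()
        )
        history.append(
            {
                "epoch": epoch,
                "learning_rate": lr,
                "train_loss": epoch_loss / max(1, n_batches),
                "val_accuracy": val_acc,
            }
        )
    return TileClassifier(backbone=backbone, head=SoftmaxHead(weights=w, bias=b)), pd.DataFrame(history)


# ---------------------------------------------------------------------------
# inference


@dataclass
class TileClassifier:
    """A backbone + trained head, the unit the segmentation stage consumes."""

    backbone: TinyBackbone
    head: SoftmaxHead

    def __post_init__(self) -> None:
        if self.backbone.n_features != self.head.n_features:
            raise ValueError(
                f"backbone feature length {self.backbone.n_features} does not match "
                f"head input length {self.head.n_features}"
            )

    def predict_proba(self, tiles: np.ndarray) -> np.ndarray:
        """Class probabilities (n, 2) for a batch of RGB tiles."""
        return self.head.predict_proba(self.backbone.embed_batch(tiles))

    def predict_proba_features(self, features: np.ndarray) -> np.ndarray:
        return self.head.predict_proba(features)

    def __call__(self, tiles: np.ndarray) -> np.ndarray:
        return self.predict_proba(tiles)


def predict_tile(tile: np.ndarray, backbone, head: SoftmaxHead) -> ClassProbabilities:
    """Classify a single 64x64 RGB tile."""
    tile = np.asarray(tile)
    if tile.shape != (64, 64, 3):
        raise ValueError(f"tile must be 64x64x3, got {tile.shape}")
    feats = np.atleast_2d(backbone.embed(tile))
    if feats.shape[1] != head.n_features:
        raise ValueError("backbone feature length does not match head")
    p = head.predict_proba(feats)[0]
    return ClassProbabilities(p_tumor=float(p[0]), p_non_tumor=float(p[1]))


# ---------------------------------------------------------------------------
# persistence


def save_model(classifier: TileClassifier, path: str | Path, config: TrainingConfig | None = None) -> None:
    """Save a model as an NPZ weight blob with an embedded JSON header."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    bb = classifier.backbone
    header = {
        "backbone": bb.name,
        "backbone_params": {
            "channels1": bb.channels1,
            "channels2": bb.channels2,
            "kernel_size": bb.kernel_size,
            "seed": bb.seed,
        },
        "n_features": classifier.head.n_features,
        "n_classes": classifier.head.n_classes,
        "classes": list(CLASSES),
        "config": config.to_dict() if config else None,
    }
    arrays = {
        "header": np.array(json.dumps(header)),
        "head_weights": classifier.head.weights,
        "head_bias": classifier.head.bias,
        "kernels1": bb.kernels1,
        "bias1": bb.bias1,
        "kernels2": bb.kernels2,
        "bias2": bb.bias2,
    }
    if classifier.head.feature_mean is not None:
        arrays["feature_mean"] = classifier.head.feature_mean
        arrays["feature_scale"] = classifier.head.feature_scale
    np.savez(path, **arrays)


def load_model(path: str | Path) -> TileClassifier:
    """Load a model saved by :func:`save_model`."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path, allow_pickle=False) as data:
        header = json.loads(str(data["header"]))
        bb = TinyBackbone(**header["backbone_params"])
        bb.kernels1 = data["kernels1"]
        bb.bias1 = data["bias1"]
        bb.kernels2 = data["kernels2"]
        bb.bias2 = data["bias2"]
        head = SoftmaxHead(
            weights=data["head_weights"],
            bias=data["head_bias"],
            feature_mean=data["feature_mean"] if "feature_mean" in data else None,
            feature_scale=data["feature_scale"] if "feature_scale" in data else None,
        )
    return TileClassifier(backbone=bb, head=head)
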
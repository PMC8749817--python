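"""Transfer-style binary image classifiers for the two screening tasks.

Two models share one architecture: a frozen convolutional feature
extractor followed by a trainable head of global average pooling, 20%
dropout, and a 2-unit softmax layer, trained with Adam on mini-batches of
32 with reshuffling every epoch.  The probe-positioning model consumes the
full swallow crop; the IRP model consumes the 100-px IRP band.  Both
inputs arrive as 299x299x3 tensors in [-1, 1].

Backbones
---------
``small_cnn_fallback`` (default)
    A three-layer convolutional network with fixed, seeded He-initialized
    kernels, kept frozen as a pure feature extractor.  It downloads
    nothing and runs deterministically on one CPU, which makes the full
    train/evaluate mechanism exercisable anywhere.
``inceptionv3_imagenet``
    Opt-in: the ImageNet-pretrained InceptionV3 feature extractor, loaded
    lazily through tensorflow/keras when such a runtime is installed.

Only the head is trainable by default, so training reduces to fitting a
softmax linear model (with inverted dropout) on frozen pooled features —
optimized here by an explicit Adam loop so batch size, shuffling, early
stopping, and seeding are fully under the package's control.

Data splitting follows the 70/15/15 convention, stratified per class with
floor rounding: a class of n items contributes floor(0.70 n) to training,
floor(0.15 n) to the test ("intermediate feedback") part and the remainder
to validation.  The validation part is never read during training; it
exists solely for the final evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .roi_pipeline import MODEL_INPUT_SIZE

INPUT_SHAPE = (MODEL_INPUT_SIZE, MODEL_INPUT_SIZE, 3)

BACKBONES = ("small_cnn_fallback", "inceptionv3_imagenet")


class ConfigurationError(ValueError):
    """Unknown backbone or inconsistent model configuration."""


# ------------------------------------------------------------------ split
@dataclass
class DatasetSplit:
    """Disjoint train / test / validation item lists.

    ``train`` feeds the optimizer; ``test`` provides the per-epoch
    intermediate feedback; ``validation`` is held out untouched until the
    final evaluation (training code never accesses it).
    """

    train: list
    test: list
    validation: list
    fractions: Tuple[float, float, float] = (0.70, 0.15, 0.15)


def stratified_split(
    items: Sequence,
    labels: Sequence,
    fractions: Tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> DatasetSplit:
    """Seeded per-class 70/15/15 split with floor rounding.

    Each class of size n gives floor(f_train * n) items to train,
    floor(f_test * n) to test, and the remainder to validation; membership
    within a class is a seeded shuffle.  Items are stored as
    ``(item, label)`` pairs in the returned split.
    """
    if len(items) != len(labels):
        raise ValueError("items and labels must have equal length")
    labels = list(labels)
    classes = sorted(set(labels))
    if not classes:
        raise ValueError("no items to split")
    rng = np.random.default_rng(seed)
    parts: Tuple[list, list, list] = ([], [], [])
    for cls in classes:
        idx = np.array([i for i, l in enumerate(labels) if l == cls])
        if idx.size == 0:
            raise ValueError(f"class {cls!r} is empty")
        rng.shuffle(idx)
        n = idx.size
        n_train = int(np.floor(fractions[0] * n))
        n_test = int(np.floor(fractions[1] * n))
        bounds = (0, n_train, n_train + n_test, n)
        for part, lo, hi in zip(parts, bounds[:-1], bounds[1:]):
            part.extend((items[i], labels[i]) for i in idx[lo:hi])
    return DatasetSplit(train=parts[0], test=parts[1], validation=parts[2], fractions=fractions)


# ------------------------------------------------------------------ model
@dataclass(frozen=True)
class ModelConfig:
    """Architecture and training protocol of one binary classifier."""

    backbone: str = "small_cnn_fallback"
    input_shape: Tuple[int, int, int] = INPUT_SHAPE
    dropout: float = 0.20
    optimizer: str = "adam"
    learning_rate: float = 0.01
    batch_size: int = 32
    shuffle_each_epoch: bool = True
    epochs: int = 20
    early_stopping_patience: int = 5
    freeze_backbone: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backbone not in BACKBONES:
            raise ConfigurationError(
                f"unknown backbone {self.backbone!r}; expected one of {BACKBONES}"
            )
        if self.optimizer != "adam":
            raise ConfigurationError("only the adam optimizer is supported")


def _maxpool(x: np.ndarray, s: int) -> np.ndarray:
    h, w, c = x.shape
    h2, w2 = h - h % s, w - w % s
    return x[:h2, :w2].reshape(h2 // s, s, w2 // s, s, c).max(axis=(1, 3))


class SmallCnnBackbone:
    """Frozen 3-conv feature extractor with seeded He-initialized kernels.

    conv3x3(16) -> ReLU -> maxpool4 -> conv3x3(32) -> ReLU -> maxpool4 ->
    conv3x3(64) -> ReLU, followed by global average pooling to 64 features.
    The kernels are fixed at construction and never trained.
    """

    n_features = 64

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        chans = (3, 16, 32, 64)
        self.kernels = []
        for cin, cout in zip(chans[:-1], chans[1:]):
            scale = np.sqrt(2.0 / (9 * cin))
            self.kernels.append(
                rng.normal(0.0, scale, (3, 3, cin, cout)).astype(np.float32)
            )

    @staticmethod
    def _conv(x: np.ndarray, k: np.ndarray) -> np.ndarray:
        win = np.lib.stride_tricks.sliding_window_view(x, (3, 3), axis=(0, 1))
        # win: (H-2, W-2, C, 3, 3); k: (3, 3, Cin, Cout)
        return np.einsum("hwcij,ijco->hwo", win, k, optimize=True)

    def features(self, tensor: np.ndarray) -> np.ndarray:
        """Pooled feature vector (64,) for one [-1, 1] H x W x 3 tensor."""
        x = np.asarray(tensor, dtype=np.float32)
        for i, k in enumerate(self.kernels):
            x = np.maximum(self._conv(x, k), 0.0)
            if i < 2:
                x = _maxpool(x, 4)
        return x.mean(axis=(0, 1))


class InceptionV3Backbone:  # pragma: no cover - requires a DL runtime
    """ImageNet-pretrained InceptionV3 feature extractor (lazy, opt-in)."""

    n_features = 2048

    def __init__(self, seed: int = 0):
        try:
            from tensorflow.keras.applications import InceptionV3
        except Exception as exc:
            raise ConfigurationError(
                "the inceptionv3_imagenet backbone needs tensorflow/keras "
                "with downloadable ImageNet weights; use small_cnn_fallback "
                "for a self-contained run"
            ) from exc
        self._model = InceptionV3(include_top=False, weights="imagenet", pooling=None)

    def features(self, tensor: np.ndarray) -> np.ndarray:
        fmap = self._model.predict(np.asarray(tensor)[None], verbose=0)[0]
        return fmap.mean(axis=(0, 1))


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class TransferClassifier:
    """Frozen backbone + trainable GAP/dropout/2-way-softmax head."""

    def __init__(self, config: ModelConfig):
        self.config = config
        if config.backbone == "small_cnn_fallback":
            self.backbone = SmallCnnBackbone(seed=config.seed)
        else:
            self.backbone = InceptionV3Backbone(seed=config.seed)
        f = self.backbone.n_features
        rng = np.random.default_rng(config.seed)
        limit = np.sqrt(6.0 / (f + 2))  # Glorot-uniform head init
        self.W = rng.uniform(-limit, limit, (f, 2))
        self.b = np.zeros(2)
        self.classes_: Optional[Tuple[str, str]] = None
        self.feat_mean = np.zeros(f)
        self.feat_std = np.ones(f)
        self.n_optimizer_steps = 0
        self.history: List[dict] = []

    # ---- feature path -------------------------------------------------
    def extract_features(self, tensors: Sequence[np.ndarray]) -> np.ndarray:
        tensors = list(tensors)
        if not tensors:
            return np.zeros((0, self.backbone.n_features))
        for t in tensors:
            if np.asarray(t).shape != self.config.input_shape:
                raise ValueError(
                    f"input shape {np.asarray(t).shape} != {self.config.input_shape}"
                )
        return np.stack([self.backbone.features(t) for t in tensors])

    def _standardize(self, feats: np.ndarray) -> np.ndarray:
        return (feats - self.feat_mean) / self.feat_std

    def predict_proba_features(self, feats: np.ndarray) -> np.ndarray:
        return _softmax(self._standardize(feats) @ self.W + self.b)

    # ---- public prediction --------------------------------------------
    def predict_proba(self, inputs) -> np.ndarray:
        arr = np.asarray(inputs)
        single = arr.ndim == 3
        batch = [arr] if single else list(arr)
        probs = self.predict_proba_features(self.extract_features(batch))
        return probs[0] if single else probs

    def predict(self, inputs):
        """Class label(s): argmax probability, ties to the smaller index."""
        probs = self.predict_proba(inputs)
        if self.classes_ is None:
            raise RuntimeError("model is untrained: no class labels attached")
        if probs.ndim == 1:
            return self.classes_[int(np.argmax(probs))]
        return [self.classes_[int(i)] for i in np.argmax(probs, axis=-1)]

    # ---- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        np.savez(
            Path(path),
            W=self.W,
            b=self.b,
            feat_mean=self.feat_mean,
            feat_std=self.feat_std,
            classes=np.asarray(self.classes_ or ("", "")),
            backbone=self.config.backbone,
            seed=self.config.seed,
        )

    @classmethod
    def load(cls, path: str | Path, config: Optional[ModelConfig] = None) -> "TransferClassifier":
        with np.load(Path(path), allow_pickle=False) as data:
            cfg = config or ModelConfig(
                backbone=str(data["backbone"]), seed=int(data["seed"])
            )
            model = cls(cfg)
            model.W = data["W"]
            model.b = data["b"]
            model.feat_mean = data["feat_mean"]
            model.feat_std = data["feat_std"]
            classes = tuple(str(c) for c in data["classes"])
            model.classes_ = classes if any(classes) else None
        return model


def build_classifier(config: ModelConfig) -> TransferClassifier:
    """Instantiate the classifier; backbone weights are frozen."""
    return TransferClassifier(config)


# --------------------------------------------------------------- training
def _encode_labels(pairs: Sequence[Tuple[np.ndarray, str]], classes: Tuple[str, str]) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    try:
        return np.array([index[l] for _, l in pairs])
    except KeyError as exc:
        raise ValueError(f"label {exc} not among classes {classes}") from exc


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    return float(-np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None)).mean())


def train(
    model: TransferClassifier,
    split: DatasetSplit,
    config: Optional[ModelConfig] = None,
) -> Tuple[TransferClassifier, List[dict]]:
    """Fit the head with Adam, batch 32, reshuffling every epoch.

    ``split.train`` holds ``(tensor, label)`` pairs used for optimization;
    ``split.test`` provides intermediate feedback — its loss/accuracy are
    logged after every epoch and drive early stopping (patience from the
    config, best-test-loss weights restored).  The validation part of the
    split is deliberately never touched here.

    Returns the trained model and the per-epoch metrics log.
    """
    config = config or model.config
    if not split.train or not split.test:
        raise ValueError("train and test split parts must be non-empty")

    classes = tuple(sorted({l for _, l in split.train}))
    if len(classes) == 1:  # single-class corner: duplicate for a 2-way head
        classes = (classes[0], f"not_{classes[0]}")
    if len(classes) != 2:
        raise ValueError(f"expected 2 classes, got {classes}")
    model.classes_ = classes  # type: ignore[assignment]

    X_train = model.extract_features([t for t, _ in split.train])
    y_train = _encode_labels(split.train, classes)
    X_test = model.extract_features([t for t, _ in split.test])
    y_test = _encode_labels(split.test, classes)

    model.feat_mean = X_train.mean(axis=0)
    model.feat_std = X_train.std(axis=0) + 1e-8
    Z_train = model._standardize(X_train)
    Z_test = model._standardize(X_test)

    rng = np.random.default_rng(config.seed)
    lr, b1, b2, eps = config.learning_rate, 0.9, 0.999, 1e-8
    mW = np.zeros_like(model.W)
    vW = np.zeros_like(model.W)
    mb = np.zeros_like(model.b)
    vb = np.zeros_like(model.b)
    t_step = 0

    best = {"loss": np.inf, "W": model.W.copy(), "b": model.b.copy(), "epoch": 0}
    patience_left = config.early_stopping_patience
    history: List[dict] = []

    n = len(y_train)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n) if config.shuffle_each_epoch else np.arange(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            Z, y = Z_train[idx], y_train[idx]
            if config.dropout > 0:
                keep = 1.0 - config.dropout
                mask = (rng.random(Z.shape) < keep) / keep  # inverted dropout
                Z = Z * mask
            probs = _softmax(Z @ model.W + model.b)
            grad = probs.copy()
            grad[np.arange(len(y)), y] -= 1.0
            grad /= len(y)
            gW = Z.T @ grad
            gb = grad.sum(axis=0)
            t_step += 1
            mW = b1 * mW + (1 - b1) * gW
            vW = b2 * vW + (1 - b2) * gW**2
            mb = b1 * mb + (1 - b1) * gb
            vb = b2 * vb + (1 - b2) * gb**2
            mW_h = mW / (1 - b1**t_step)
            vW_h = vW / (1 - b2**t_step)
            mb_h = mb / (1 - b1**t_step)
            vb_h = vb / (1 - b2**t_step)
            model.W -= lr * mW_h / (np.sqrt(vW_h) + eps)
            model.b -= lr * mb_h / (np.sqrt(vb_h) + eps)
            model.n_optimizer_steps += 1

        test_probs = _softmax(Z_test @ model.W + model.b)
        test_loss = _cross_entropy(test_probs, y_test)
        test_acc = float((test_probs.argmax(axis=1) == y_test).mean())
        train_probs = _softmax(Z_train @ model.W + model.b)
        history.append(
            {
                "epoch": epoch,
                "train_loss": _cross_entropy(train_probs, y_train),
                "train_accuracy": float((train_probs.argmax(axis=1) == y_train).mean()),
                "test_loss": test_loss,
                "test_accuracy": test_acc,
            }
        )
        if test_loss < best["loss"] - 1e-9:
            best = {"loss": test_loss, "W": model.W.copy(), "b": model.b.copy(), "epoch": epoch}
            patience_left = config.early_stopping_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break

    model.W, model.b = best["W"], best["b"]
    model.history = history
    return model, history
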
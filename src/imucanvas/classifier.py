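"""Baseline CNN, split protocols, and classification metrics.

The reference classifier is intentionally plain: two convolutional layers of
128 filters (3x3), each followed by 2x2 max-pooling with stride 2, then one
dense layer of 256 units and a softmax output, trained with cross-entropy,
Adam, and early stopping on validation loss.  The discriminative work is
meant to be done by the image encoding, not the network.

Split protocols are stratified and seeded: k-fold cross-validation or
train/(val/)test fractions.  Metrics are computed per class from one-vs-rest
confusion counts:

    accuracy = (TP+TN)/(TP+TN+FP+FN)      precision = TP/(TP+FP)
    recall   = TP/(TP+FN)                 F1 = 2*P*R/(P+R)

and macro-averaged for the headline number.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import nn

__all__ = [
    "CNNConfig",
    "CNNModel",
    "ConfusionCounts",
    "MetricsReport",
    "TrainResult",
    "build_model",
    "stratified_kfold",
    "stratified_fractions",
    "train",
    "evaluate",
    "confusion_from_predictions",
    "metrics_from_confusion",
]


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and training hyperparameters.

    The architecture defaults mirror the baseline (128+128 filters, 3x3
    kernels, 2x2/stride-2 pools, 256 dense units, softmax output); training
    hyperparameters are explicit configuration with common defaults.
    """

    conv_filters: tuple[int, int] = (128, 128)
    kernel_size: int = 3
    dense_units: int = 256
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 100
    patience: int = 10  # early stopping on validation loss, restore best
    seed: int = 0

    def with_seed(self, seed: int) -> "CNNConfig":
        return replace(self, seed=seed)


class CNNModel:
    """conv-pool-conv-pool-dense-softmax network over uint8/float rasters."""

    def __init__(self, cfg: CNNConfig, input_shape: tuple[int, int, int], n_classes: int):
        h, w, c = input_shape
        k = cfg.kernel_size
        h1, w1 = (h - k + 1) // 2, (w - k + 1) // 2
        h2, w2 = (h1 - k + 1) // 2, (w1 - k + 1) // 2
        if h2 < 1 or w2 < 1:
            raise ValueError(
                f"input {h}x{w} too small for two {k}x{k} conv + 2x2 pool blocks"
            )
        self.cfg = cfg
        self.input_shape = input_shape
        self.n_classes = n_classes
        rng = np.random.default_rng(cfg.seed)
        f1, f2 = cfg.conv_filters
        self.net = nn.Sequential([
            nn.Conv2D(c, f1, k, rng),
            nn.ReLU(),
            nn.MaxPool2(),
            nn.Conv2D(f1, f2, k, rng),
            nn.ReLU(),
            nn.MaxPool2(),
            nn.Flatten(),
            nn.Dense(h2 * w2 * f2, cfg.dense_units, rng),
            nn.ReLU(),
            nn.Dense(cfg.dense_units, n_classes, rng),
        ])
        self.classes_: np.ndarray | None = None
        self.history: dict[str, list[float]] = {}

    # -- helpers -----------------------------------------------------------

    @property
    def param_count(self) -> int:
        return self.net.param_count()

    @staticmethod
    def _prepare(images: np.ndarray) -> np.ndarray:
        """uint8 rasters -> float32 in [0, 1], channel axis guaranteed."""
        x = np.asarray(images)
        if x.ndim == 3:
            x = x[..., None]
        x = x.astype(np.float32)
        if x.max() > 1.0:
            x = x / 255.0
        return x

    def _encode_labels(self, labels: Sequence) -> np.ndarray:
        if self.classes_ is None:
            self.classes_ = np.array(sorted(set(labels)))
        index = {c: i for i, c in enumerate(self.classes_)}
        return np.array([index[l] for l in labels])

    def predict_proba(self, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
        x = self._prepare(images)
        out = [
            nn.softmax(self.net.forward(x[i:i + batch_size]))
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(out, axis=0)

    def predict(self, images: np.ndarray) -> np.ndarray:
        assert self.classes_ is not None, "model is not fitted"
        return self.classes_[self.predict_proba(images).argmax(axis=1)]

    # -- training ----------------------------------------------------------

    def fit(
        self,
        images: np.ndarray,
        labels: Sequence,
        val_images: np.ndarray,
        val_labels: Sequence,
    ) -> dict[str, list[float]]:
        cfg = self.cfg
        x = self._prepare(images)
        y = self._encode_labels(labels)
        xv = self._prepare(val_images)
        yv = self._encode_labels(val_labels)
        opt = nn.Adam(self.net, lr=cfg.learning_rate)
        rng = np.random.default_rng(cfg.seed + 1)
        history: dict[str, list[float]] = {
            "train_loss": [], "val_loss": [], "val_accuracy": []
        }
        best_loss, best_weights, since_best = np.inf, self.net.get_weights(), 0
        for _epoch in range(cfg.max_epochs):
            order = rng.permutation(len(x))
            losses = []
            for i in range(0, len(x), cfg.batch_size):
                idx = order[i:i + cfg.batch_size]
                logits = self.net.forward(x[idx])
                loss, dlogits = nn.softmax_cross_entropy(logits, y[idx])
                self.net.backward(dlogits)
                opt.step()
                losses.append(loss)
            val_logits = np.concatenate(
                [self.net.forward(xv[i:i + 256]) for i in range(0, len(xv), 256)]
            )
            val_loss, _ = nn.softmax_cross_entropy(val_logits, yv)
            val_acc = float((val_logits.argmax(axis=1) == yv).mean())
            history["train_loss"].append(float(np.mean(losses)))
            history["val_loss"].append(val_loss)
            history["val_accuracy"].append(val_acc)
            if val_loss < best_loss - 1e-6:
                best_loss, best_weights, since_best = val_loss, self.net.get_weights(), 0
            else:
                since_best += 1
                if since_best >= cfg.patience:
                    break
        self.net.set_weights(best_weights)
        self.history = history
        return history


def build_model(
    cfg: CNNConfig, input_shape: tuple[int, int, int], n_classes: int
) -> CNNModel:
    """Instantiate the baseline CNN for the given raster shape."""
    return CNNModel(cfg, input_shape, n_classes)


# ---------------------------------------------------------------------------
# split protocols


def stratified_kfold(
    labels: Sequence, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold: disjoint, exhaustive, per-class balanced.

    Returns ``k`` pairs of (train_indices, test_indices).  Within each class
    the shuffled indices are dealt round-robin, so per-class fold sizes
    differ by at most one item.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    out = []
    for j in range(k):
        test = np.sort(np.array(folds[j], dtype=int))
        train = np.sort(np.concatenate([folds[m] for m in range(k) if m != j]).astype(int))
        out.append((train, test))
    return out


def stratified_fractions(
    labels: Sequence, fractions: Sequence[float], seed: int
) -> tuple[np.ndarray, ...]:
    """Seeded stratified split into len(fractions) parts (must sum to 1)."""
    fractions = list(fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[] for _ in fractions]
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        edges = np.floor(np.cumsum(fractions) * len(idx)).astype(int)
        start = 0
        for p, stop in enumerate(edges):
            parts[p].extend(idx[start:stop].tolist())
            start = stop
        # any remainder from flooring goes to the first part
        parts[0].extend(idx[start:].tolist())
    return tuple(np.sort(np.array(p, dtype=int)) for p in parts)


# ---------------------------------------------------------------------------
# metrics


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest TP/FP/FN/TN per class over one evaluated set."""

    counts: Mapping[str, tuple[int, int, int, int]]  # label -> (TP, FP, FN, TN)
    n_total: int

    def __getitem__(self, label: str) -> tuple[int, int, int, int]:
        return self.counts[label]


@dataclass(frozen=True)
class MetricsReport:
    """Per-class and macro-averaged accuracy/precision/recall/F1."""

    per_class: Mapping[str, dict[str, float]]
    macro: dict[str, float]
    overall_accuracy: float


def confusion_from_predictions(y_true: Sequence, y_pred: Sequence) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    n = len(y_true)
    counts = {}
    for cls in sorted(set(y_true.tolist()) | set(y_pred.tolist())):
        tp = int(np.sum((y_true == cls) & (y_pred == cls)))
        fp = int(np.sum((y_true != cls) & (y_pred == cls)))
        fn = int(np.sum((y_true == cls) & (y_pred != cls)))
        counts[str(cls)] = (tp, fp, fn, n - tp - fp - fn)
    return ConfusionCounts(counts=counts, n_total=n)


def metrics_from_confusion(conf: ConfusionCounts) -> MetricsReport:
    per_class = {}
    for cls, (tp, fp, fn, tn) in conf.counts.items():
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (
            2 * precision * recall / (precision + recall)
            if precision + recall
            else 0.0
        )
        per_class[cls] = {
            "accuracy": (tp + tn) / (tp + tn + fp + fn),
            "precision": precision,
            "recall": recall,
            "f1": f1,
        }
    macro = {
        m: float(np.mean([v[m] for v in per_class.values()]))
        for m in ("accuracy", "precision", "recall", "f1")
    }
    overall = sum(tp for tp, _, _, _ in conf.counts.values()) / conf.n_total
    return MetricsReport(per_class=per_class, macro=macro, overall_accuracy=overall)


def evaluate(
    model: CNNModel, images: np.ndarray, labels: Sequence
) -> tuple[ConfusionCounts, MetricsReport]:
    """Confusion counts and the standard metrics on a labeled set."""
    pred = model.predict(images)
    conf = confusion_from_predictions(np.asarray(labels).astype(str), pred.astype(str))
    return conf, metrics_from_confusion(conf)


# ---------------------------------------------------------------------------
# protocol driver


@dataclass
class TrainResult:
    """Outcome of one training protocol run."""

    models: list[CNNModel]
    histories: list[dict[str, list[float]]]
    confusion: ConfusionCounts
    metrics: MetricsReport
    split: dict = field(default_factory=dict)


def _fit_once(
    cfg: CNNConfig,
    images: np.ndarray,
    labels: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    seed: int,
    val_fraction: float = 0.1,
    val_idx: np.ndarray | None = None,
) -> tuple[CNNModel, dict, np.ndarray, np.ndarray]:
    input_shape = images.shape[1:] if images.ndim == 4 else images.shape[1:] + (1,)
    n_classes = len(set(labels.tolist()))
    model = build_model(cfg.with_seed(seed), tuple(input_shape), n_classes)
    if val_idx is None:
        # hold out part of the training data for early stopping
        tr, val = stratified_fractions(
            labels[train_idx], (1 - val_fraction, val_fraction), seed + 1
        )
        tr_idx, val_idx = train_idx[tr], train_idx[val]
    else:
        tr_idx = train_idx
    history = model.fit(
        images[tr_idx], labels[tr_idx], images[val_idx], labels[val_idx]
    )
    pred = model.predict(images[test_idx])
    return model, history, labels[test_idx], pred


def train(
    cfg: CNNConfig,
    images: np.ndarray,
    labels: Sequence,
    split: Mapping[str, object],
    seed: int = 0,
) -> TrainResult:
    """Run a full split protocol and return aggregated test metrics.

    ``split`` is either ``{"kfold": k}`` or ``{"fractions": (...)}`` with 2
    (train/test) or 3 (train/val/test) stratified fractions.  Requires at
    least 2 classes with at least 2 examples each.
    """
    labels = np.asarray(labels).astype(str)
    class_counts = {c: int((labels == c).sum()) for c in set(labels.tolist())}
    if len(class_counts) < 2 or min(class_counts.values()) < 2:
        raise ValueError(f"degenerate split: class counts {class_counts}")
    images = np.asarray(images)

    y_true_all: list[np.ndarray] = []
    y_pred_all: list[np.ndarray] = []
    models, histories = [], []
    if "kfold" in split:
        k = int(split["kfold"])  # type: ignore[arg-type]
        for f, (tr, te) in enumerate(stratified_kfold(labels, k, seed)):
            model, hist, yt, yp = _fit_once(cfg, images, labels, tr, te, seed + f)
            models.append(model)
            histories.append(hist)
            y_true_all.append(yt)
            y_pred_all.append(yp)
    elif "fractions" in split:
        fracs = tuple(split["fractions"])  # type: ignore[arg-type]
        parts = stratified_fractions(labels, fracs, seed)
        if len(fracs) == 2:
            tr, te = parts
            model, hist, yt, yp = _fit_once(cfg, images, labels, tr, te, seed)
        elif len(fracs) == 3:
            tr, va, te = parts
            model, hist, yt, yp = _fit_once(
                cfg, images, labels, tr, te, seed, val_idx=va
            )
        else:
            raise ValueError("fractions must have 2 or 3 entries")
        models.append(model)
        histories.append(hist)
        y_true_all.append(yt)
        y_pred_all.append(yp)
    else:
        raise ValueError("split must contain 'kfold' or 'fractions'")

    conf = confusion_from_predictions(
        np.concatenate(y_true_all), np.concatenate(y_pred_all)
    )
    return TrainResult(
        models=models,
        histories=histories,
        confusion=conf,
        metrics=metrics_from_confusion(conf),
        split=dict(split),
    )
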
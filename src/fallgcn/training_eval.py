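"""Training loop and evaluation metrics.

The optimisation recipe is the standard one for skeleton GCNs: SGD with
Nesterov momentum 0.9, weight decay 5e-4, cross-entropy loss, batch size
16, 60 epochs, initial learning rate 0.1 decaying by 10x at epochs 20 and
40, sequences replay-padded to 300 frames, optional random-rotation
augmentation.  The adjacency tensor is frozen for the first 10 epochs and
learnable afterwards.

Evaluation fills a K x K confusion matrix (argmax prediction, ties to the
lowest class index), collapses it to fall-vs-rest, and reports sensitivity
TP/(TP+FN), specificity TN/(TN+FP) and accuracy (TP+TN)/total.  A ratio
with a zero denominator is reported as NaN with a warning, never as 0.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from .feature_encoding import encode_batch
from .network import (ModelConfig, ModelParams, forward_logits,
                      parameter_count, set_adjacency_trainable)
from .skeleton_io import fit_length, normalize_to_center, rotate_augment
from .synthetic_data import CLASS_NAMES

log = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "ConfusionCounts", "Metrics", "lr_at", "train",
    "evaluate", "predict", "ablation_grid", "train_test_split",
    "FALL_CLASS",
]

FALL_CLASS = CLASS_NAMES.index("fall")


@dataclass
class TrainConfig:
    """Optimisation hyperparameters (defaults follow the full recipe)."""

    epochs: int = 60
    lr0: float = 0.1
    decay_epochs: tuple[int, ...] = (20, 40)
    decay_factor: float = 10.0
    momentum: float = 0.9
    weight_decay: float = 0.0005
    batch_size: int = 16
    target_T: int = 300
    seed: int = 0
    augment: bool = True
    normalize: bool = True
    max_rotation: float = float(np.deg2rad(17.0))

    def __post_init__(self):
        self.decay_epochs = tuple(self.decay_epochs)
        if self.epochs < 1 or self.batch_size < 1 or self.target_T < 1:
            raise ValueError("epochs, batch_size, target_T must be positive")
        if self.lr0 < 0 or self.decay_factor <= 0:
            raise ValueError("bad learning-rate settings")
        if any(not (0 <= e < self.epochs) for e in self.decay_epochs):
            raise ValueError("decay_epochs must lie inside [0, epochs)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["decay_epochs"] = list(self.decay_epochs)
        return d


@dataclass
class ConfusionCounts:
    """K x K confusion matrix (rows true, columns predicted) plus the
    fall-vs-rest binary collapse."""

    matrix: np.ndarray
    positive_class: int

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.int64)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (self.matrix < 0).any():
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    def binary(self) -> tuple[int, int, int, int]:
        """(TP, FP, TN, FN) with the positive class = fall."""
        p = self.positive_class
        tp = int(self.matrix[p, p])
        fn = int(self.matrix[p].sum() - tp)
        fp = int(self.matrix[:, p].sum() - tp)
        tn = int(self.matrix.sum() - tp - fn - fp)
        return tp, fp, tn, fn


@dataclass
class Metrics:
    sensitivity: float
    specificity: float
    accuracy: float

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int) -> "Metrics":
        def ratio(num, den, name):
            if den == 0:
                warnings.warn(f"{name} undefined (zero denominator)",
                              RuntimeWarning, stacklevel=3)
                return float("nan")
            return num / den
        return cls(sensitivity=ratio(tp, tp + fn, "sensitivity"),
                   specificity=ratio(tn, tn + fp, "specificity"),
                   accuracy=ratio(tp + tn, tp + tn + fp + fn, "accuracy"))

    def to_dict(self) -> dict:
        return asdict(self)


def lr_at(epoch: int, cfg: TrainConfig) -> float:
    """Step-decay schedule: lr0 / factor^(number of decay epochs <= epoch).
    The new rate applies from the decay epoch itself (0-based)."""
    if not (0 <= epoch < cfg.epochs):
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    n = sum(1 for e in cfg.decay_epochs if e <= epoch)
    return cfg.lr0 / cfg.decay_factor ** n


def _prepare(seq, cfg: TrainConfig, rng: np.random.Generator | None):
    if cfg.normalize:
        seq = normalize_to_center(seq)
    out = fit_length(seq, cfg.target_T)
    if rng is not None and cfg.augment:
        out = rotate_augment(out, cfg.max_rotation,
                             seed=int(rng.integers(0, 2**31 - 1)))
    return out


def train(params: ModelParams, dataset, cfg: TrainConfig,
          log_sink=None) -> tuple[ModelParams, list[dict]]:
    """Train in place; returns ``(params, history)``.

    ``history`` holds one record per epoch: epoch, lr, mean loss, training
    accuracy, and whether the adjacency was trainable.  Identical seeds
    give identical histories.
    """
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty training dataset")
    K = params.config.num_classes
    labels = []
    for seq in dataset:
        if seq.label is None or not (0 <= seq.label < K):
            raise ValueError(f"label {seq.label!r} outside [0, {K})")
        labels.append(seq.label)
    labels = np.asarray(labels)

    rng = np.random.default_rng(cfg.seed)
    opt = ad.SGD(list(params.named_tensors().values()), lr=cfg.lr0,
                 momentum=cfg.momentum, weight_decay=cfg.weight_decay,
                 nesterov=True)
    history = []
    n = len(dataset)
    for epoch in range(cfg.epochs):
        set_adjacency_trainable(params, epoch)
        lr = lr_at(epoch, cfg)
        opt.lr = lr
        order = rng.permutation(n)
        losses, correct = [], 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            batch = [_prepare(dataset[i], cfg, rng) for i in idx]
            y = labels[idx]
            encoded = encode_batch(batch, params.encoder)
            logits, _ = forward_logits(params, encoded, training=True)
            loss = ad.cross_entropy(logits, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == y).sum())
        rec = {"epoch": epoch, "lr": lr,
               "loss": float(np.mean(losses)),
               "train_accuracy": correct / n,
               "adjacency_trainable": params.adjacency_trainable}
        history.append(rec)
        params.epoch = epoch + 1
        msg = (f"epoch {epoch:3d}  lr {lr:.4g}  loss {rec['loss']:.4f}  "
               f"acc {rec['train_accuracy']:.3f}")
        if log_sink is not None:
            print(msg, file=log_sink)
        else:
            log.info(msg)
    return params, history


def predict(params: ModelParams, dataset, target_T: int | None = None,
            batch_size: int = 16, normalize: bool = True) -> np.ndarray:
    """Argmax class predictions (ties resolve to the lowest index).

    Applies the same centre-joint normalisation and length fitting as
    training."""
    dataset = list(dataset)
    tT = target_T or 300
    preds = np.empty(len(dataset), dtype=np.intp)
    for start in range(0, len(dataset), batch_size):
        chunk = dataset[start:start + batch_size]
        if normalize:
            chunk = [normalize_to_center(s) for s in chunk]
        batch = [fit_length(s, tT) for s in chunk]
        encoded = encode_batch(batch, params.encoder)
        logits, _ = forward_logits(params, encoded, training=False)
        preds[start:start + len(chunk)] = logits.data.argmax(axis=1)
    return preds


def evaluate(params: ModelParams, dataset,
             positive_class: int | None = None,
             target_T: int | None = None) -> tuple[ConfusionCounts, Metrics]:
    """Confusion matrix + fall-vs-rest sensitivity/specificity/accuracy.

    The positive class defaults to the fall class of the six-class setup,
    or the last class when the model has fewer classes."""
    dataset = list(dataset)
    if not dataset:
        raise ValueError("empty evaluation dataset")
    K = params.config.num_classes
    if positive_class is None:
        positive_class = FALL_CLASS if FALL_CLASS < K else K - 1
    preds = predict(params, dataset, target_T=target_T)
    matrix = np.zeros((K, K), dtype=np.int64)
    for seq, pred in zip(dataset, preds):
        matrix[seq.label, pred] += 1
    counts = ConfusionCounts(matrix, positive_class)
    metrics = Metrics.from_counts(*counts.binary())
    return counts, metrics


def train_test_split(dataset, test_fraction: float = 0.2, seed: int = 0):
    """Stratified split by label, deterministic in ``seed``."""
    rng = np.random.default_rng(seed)
    by_label: dict[int, list] = {}
    for seq in dataset:
        by_label.setdefault(seq.label, []).append(seq)
    train_set, test_set = [], []
    for label in sorted(by_label):
        group = by_label[label]
        order = rng.permutation(len(group))
        n_test = max(1, int(round(test_fraction * len(group))))
        for j, i in enumerate(order):
            (test_set if j < n_test else train_set).append(group[i])
    return train_set, test_set


def ablation_grid(base_model_config: ModelConfig, train_cfg: TrainConfig,
                  dataset, variants=None, seed: int = 0, log_sink=None):
    """Train + evaluate a grid of configuration variants on one dataset.

    ``variants`` is a list of dicts of ModelConfig field overrides; the
    default grid toggles subgraph division/attention and sweeps every
    subset of the MTCN kernels (including none).  Each row reports the
    variant, its parameter count, and the held-out metrics.
    """
    if variants is None:
        variants = []
        for div, att in ((True, False), (False, True), (True, True)):
            variants.append({"use_subgraph_division": div,
                             "use_subgraph_attention": att})
        kernels = base_model_config.mtcn_kernels
        subsets = [()]
        for r in range(1, len(kernels) + 1):
            from itertools import combinations
            subsets.extend(combinations(kernels, r))
        for sub in subsets:
            variants.append({"mtcn_kernels": tuple(sub)})
    train_set, test_set = train_test_split(dataset, seed=seed)
    rows = []
    for overrides in variants:
        cfg_dict = base_model_config.to_dict()
        cfg_dict.update(overrides)
        mc = ModelConfig.from_dict(cfg_dict)
        params = ModelParams(mc, seed=seed)
        params, history = train(params, train_set, train_cfg,
                                log_sink=log_sink)
        _, metrics = evaluate(params, test_set,
                              target_T=train_cfg.target_T)
        rows.append({"variant": dict(overrides),
                     "parameter_count": parameter_count(mc),
                     "metrics": metrics.to_dict(),
                     "final_train_loss": history[-1]["loss"]})
    return rows


# ----------------------------------------------------------------- reporting

def write_history_csv(history, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["epoch", "lr", "loss", "train_accuracy",
                            "adjacency_trainable"])
        writer.writeheader()
        writer.writerows(history)


def write_confusion_csv(counts: ConfusionCounts, path,
                        class_names=CLASS_NAMES) -> None:
    K = counts.matrix.shape[0]
    names = list(class_names)[:K] if len(class_names) >= K else [
        f"class_{i}" for i in range(K)]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["true\\pred"] + names)
        for i in range(K):
            writer.writerow([names[i]] + counts.matrix[i].tolist())


def write_metrics_json(metrics: Metrics, counts: ConfusionCounts,
                       path) -> None:
    tp, fp, tn, fn = counts.binary()
    doc = dict(metrics.to_dict())
    doc.update({"TP": tp, "FP": fp, "TN": tn, "FN": fn,
                "n": counts.total})
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, allow_nan=True)
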
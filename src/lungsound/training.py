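"""Training protocol: stratified splitting, accumulated-gradient AdamW
optimization, early stopping, and learning-rate scheduling.

The optimizer steps once per ``grad_accum`` micro-batches (base batch 8,
accumulation 4 -> effective batch 32 at the defaults). Validation loss
drives both early stopping (patience 10) and, under the default plateau
schedule, a 0.1x learning-rate cut after 5 stagnant epochs; a cosine
decay schedule is available instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .features import FeatureBundle
from .metrics import MetricsReport, compute_metrics
from .model import ModelOutput, RespiratoryModel
from .nn import AdamW, cross_entropy

__all__ = [
    "TrainConfig", "SplitIndices", "TrainHistory", "EarlyStopper",
    "PlateauScheduler", "cosine_lr", "stratified_split", "train",
    "evaluate", "predict", "one_hot",
]


@dataclass
class TrainConfig:
    lr: float = 1e-5
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 0.01
    base_batch: int = 8
    grad_accum: int = 4
    max_epochs: int = 200
    patience: int = 10
    scheduler: str = "plateau"      # {"plateau", "cosine"}
    plateau_factor: float = 0.1
    plateau_patience: int = 5
    seed: int = 0

    @property
    def effective_batch(self) -> int:
        return self.base_batch * self.grad_accum


@dataclass
class SplitIndices:
    train: np.ndarray
    val: np.ndarray
    test: np.ndarray

    def all_indices(self) -> np.ndarray:
        return np.concatenate([self.train, self.val, self.test])


def stratified_split(labels: Sequence, ratios: tuple[float, float, float] = (0.6, 0.2, 0.2),
                     seed: int = 0) -> SplitIndices:
    """Per-class shuffled allocation with largest-remainder rounding."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for lab in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == lab)
        if idx.size < 3:
            raise ValueError(f"class {lab!r} has fewer than 3 members")
        rng.shuffle(idx)
        exact = np.array(ratios) * idx.size
        counts = np.floor(exact).astype(int)
        remainder = idx.size - counts.sum()
        # ties broken toward the earlier split (train, then val, then test)
        order = np.argsort(-(exact - counts), kind="stable")
        for j in order[:remainder]:
            counts[j] += 1
        start = 0
        for part, cnt in zip(parts, counts):
            part.extend(idx[start:start + cnt].tolist())
            start += cnt
    return SplitIndices(*(np.array(sorted(p), dtype=int) for p in parts))


class EarlyStopper:
    """Stop after ``patience`` epochs without validation-loss improvement."""

    def __init__(self, patience: int, min_delta: float = 0.0):
        self.patience, self.min_delta = patience, min_delta
        self.best = np.inf
        self.stale = 0

    def update(self, val_loss: float) -> bool:
        """Returns True when training should stop."""
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


class PlateauScheduler:
    """Multiply the LR by ``factor`` after ``patience`` stagnant epochs."""

    def __init__(self, lr: float, factor: float = 0.1, patience: int = 5,
                 min_lr: float = 1e-8):
        self.lr, self.factor, self.patience, self.min_lr = lr, factor, patience, min_lr
        self.best = np.inf
        self.stale = 0

    def update(self, val_loss: float) -> float:
        if val_loss < self.best:
            self.best = val_loss
            self.stale = 0
        else:
            self.stale += 1
            if self.stale >= self.patience:
                self.lr = max(self.lr * self.factor, self.min_lr)
                self.stale = 0
        return self.lr


def cosine_lr(lr0: float, epoch: int, max_epochs: int) -> float:
    return lr0 * 0.5 * (1 + np.cos(np.pi * min(epoch, max_epochs) / max_epochs))


def one_hot(labels: Sequence, classes: Sequence) -> np.ndarray:
    index = {c: i for i, c in enumerate(classes)}
    out = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        out[i, index[lab]] = 1.0
    return out


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    steps: int = 0
    stopped_early: bool = False
    step_losses: list[float] = field(default_factory=list)


def _batch_views(bundle: FeatureBundle, idx: np.ndarray):
    return bundle.x_mfcc[idx], bundle.x_wav[idx], bundle.x_mel[idx]


def _forward_loss(model: RespiratoryModel, bundle: FeatureBundle,
                  targets: np.ndarray, idx: np.ndarray):
    out = model(*_batch_views(bundle, idx))
    return out, cross_entropy(out.logits, targets[idx])


def validation_loss(model: RespiratoryModel, bundle: FeatureBundle,
                    targets: np.ndarray, batch: int = 16) -> float:
    model.eval()
    n = bundle.batch_size
    total = 0.0
    for start in range(0, n, batch):
        idx = np.arange(start, min(start + batch, n))
        _, loss = _forward_loss(model, bundle, targets, idx)
        total += float(loss.data) * idx.size
    model.train()
    return total / n


def train(model: RespiratoryModel, train_bundle: FeatureBundle, train_targets: np.ndarray,
          val_bundle: Optional[FeatureBundle] = None,
          val_targets: Optional[np.ndarray] = None,
          cfg: Optional[TrainConfig] = None,
          max_steps: Optional[int] = None,
          stop_at_val_accuracy: Optional[float] = None,
          augment_fn: Optional[Callable[[FeatureBundle, np.ndarray, np.random.Generator],
                                        tuple[FeatureBundle, np.ndarray]]] = None,
          ) -> TrainHistory:
    """Accumulated-gradient training loop with early stopping.

    ``train_targets`` rows are probability vectors (soft labels from
    mixup/cutmix are supported directly). ``augment_fn``, when given, maps
    (bundle, targets, rng) to an augmented epoch view. ``max_steps`` and
    ``stop_at_val_accuracy`` bound desk-scale runs.
    """
    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()

    # lazy projections materialize on the first forward pass
    model.train()
    _ = model(*_batch_views(train_bundle, np.array([0])))
    optimizer = AdamW(model.parameters(), lr=cfg.lr, betas=cfg.betas,
                      weight_decay=cfg.weight_decay)
    stopper = EarlyStopper(cfg.patience)
    plateau = PlateauScheduler(cfg.lr, cfg.plateau_factor, cfg.plateau_patience)

    n = train_bundle.batch_size
    for epoch in range(cfg.max_epochs):
        if cfg.scheduler == "cosine":
            optimizer.lr = cosine_lr(cfg.lr, epoch, cfg.max_epochs)
        bundle, targets = train_bundle, train_targets
        if augment_fn is not None:
            bundle, targets = augment_fn(train_bundle, train_targets, rng)
        order = rng.permutation(bundle.batch_size)
        epoch_loss, micro = 0.0, 0
        optimizer.zero_grad()
        for start in range(0, bundle.batch_size, cfg.base_batch):
            idx = order[start:start + cfg.base_batch]
            out, loss = _forward_loss(model, bundle, targets, idx)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"NaN/inf loss at epoch {epoch}, micro-batch indices {idx.tolist()}")
            (loss * (1.0 / cfg.grad_accum)).backward()
            epoch_loss += float(loss.data) * idx.size
            history.step_losses.append(float(loss.data))
            micro += 1
            if micro % cfg.grad_accum == 0:
                optimizer.step()
                optimizer.zero_grad()
                history.steps += 1
                if max_steps is not None and history.steps >= max_steps:
                    break
        if micro % cfg.grad_accum:  # flush a trailing partial accumulation
            optimizer.step()
            optimizer.zero_grad()
            history.steps += 1
        history.train_loss.append(epoch_loss / n)

        if val_bundle is not None and val_targets is not None:
            vloss = validation_loss(model, val_bundle, val_targets)
            history.val_loss.append(vloss)
            if cfg.scheduler == "plateau":
                optimizer.lr = plateau.update(vloss)
            history.lr.append(optimizer.lr)
            if stop_at_val_accuracy is not None:
                acc = evaluate_accuracy(model, val_bundle, val_targets)
                if acc >= stop_at_val_accuracy:
                    break
            if stopper.update(vloss):
                history.stopped_early = True
                break
        else:
            history.lr.append(optimizer.lr)
        if max_steps is not None and history.steps >= max_steps:
            break
    return history


def predict(model: RespiratoryModel, bundle: FeatureBundle,
            batch: int = 16) -> np.ndarray:
    """Class-index predictions (argmax of the softmax)."""
    model.eval()
    preds = []
    n = bundle.batch_size
    for start in range(0, n, batch):
        idx = np.arange(start, min(start + batch, n))
        out = model(*_batch_views(bundle, idx))
        preds.append(out.probabilities.argmax(axis=1))
    model.train()
    return np.concatenate(preds)


def evaluate_accuracy(model: RespiratoryModel, bundle: FeatureBundle,
                      targets: np.ndarray) -> float:
    """Fraction of argmax predictions matching argmax targets."""
    preds = predict(model, bundle)
    return float(np.mean(preds == targets.argmax(axis=1)))


def evaluate(model: RespiratoryModel, bundle: FeatureBundle, targets: np.ndarray,
             class_names: Sequence) -> MetricsReport:
    preds = predict(model, bundle)
    names = list(class_names)
    y_pred = [names[p] for p in preds]
    y_true = [names[t] for t in targets.argmax(axis=1)]
    return compute_metrics(y_true, y_pred, labels=names)
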
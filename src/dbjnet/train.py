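"""Training loop: Adam, plateau-triggered learning-rate decay, early
stopping, and best-on-validation checkpointing.

The learning rate starts at 1e-4 and is multiplied by 0.9 whenever the
validation loss has gone ``plateau_patience`` consecutive epochs without
improving. The weights of the epoch with the highest validation accuracy
are checkpointed and restored at the end; training stops early when
validation accuracy has not improved for ``early_stop_patience`` epochs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import DBJNet
from .preprocess import EpochSet


@dataclass(frozen=True)
class TrainConfig:
    lr_init: float = 1e-4
    plateau_patience: int = 14
    lr_decay_factor: float = 0.9
    batch_size: int = 32
    max_epochs: int = 200
    early_stop_patience: int = 30
    seed: int = 0
    #: weight classes by inverse frequency in the loss (off by default)
    class_weighting: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.lr_decay_factor < 1:
            raise ValueError("lr_decay_factor must lie in (0, 1)")
        if self.batch_size < 1 or self.plateau_patience < 1 \
                or self.early_stop_patience < 1:
            raise ValueError("batch size and patience values must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = -1
    best_val_accuracy: float = float("nan")

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def lr_plateau_step(current_lr: float, val_loss_history: list[float],
                    patience: int, factor: float) -> float:
    """New learning rate after the latest epoch.

    The loss history's best (lowest, first occurrence) epoch anchors the
    plateau count; every ``patience`` consecutive non-improving epochs the
    rate is multiplied by ``factor``, so a plateau of 2*patience epochs
    decays it twice.
    """
    if not val_loss_history:
        raise ValueError("val_loss_history must be non-empty")
    losses = np.asarray(val_loss_history, dtype=float)
    best_idx = int(np.argmin(losses))
    n_no_improve = len(losses) - 1 - best_idx
    if n_no_improve > 0 and n_no_improve % patience == 0:
        return factor * current_lr
    return current_lr


def _remap_labels(train_set: EpochSet, val_set: EpochSet
                  ) -> tuple[np.ndarray, np.ndarray, list[int]]:
    classes = sorted(np.unique(train_set.labels).tolist())
    if sorted(np.unique(val_set.labels).tolist()) != classes:
        raise ValueError("train and validation label sets differ")
    lut = {c: i for i, c in enumerate(classes)}
    y_tr = np.array([lut[y] for y in train_set.labels])
    y_va = np.array([lut[y] for y in val_set.labels])
    return y_tr, y_va, classes


def _batch_logits(model: DBJNet, x: np.ndarray,
                  batch_size: int = 256) -> np.ndarray:
    out = [model.forward(x[i:i + batch_size])
           for i in range(0, len(x), batch_size)]
    return np.concatenate(out, axis=0)


def evaluate_loss_acc(model: DBJNet, x: np.ndarray, y: np.ndarray
                      ) -> tuple[float, float]:
    logits = _batch_logits(model, x)
    loss, _ = nn.softmax_cross_entropy(logits, y)
    acc = float((logits.argmax(axis=1) == y).mean())
    return loss, acc


def train_model(model: DBJNet, train_set: EpochSet, val_set: EpochSet,
                config: TrainConfig = TrainConfig()
                ) -> tuple[DBJNet, TrainHistory]:
    """Minimize cross-entropy with Adam; return the model restored to its
    best-validation-accuracy weights together with the epoch history."""
    if len(train_set) == 0 or len(val_set) == 0:
        raise ValueError("empty training or validation split")
    y_tr, y_va, classes = _remap_labels(train_set, val_set)
    if len(classes) < 2:
        raise ValueError("training set contains a single class")
    if len(classes) != model.config.n_classes:
        raise ValueError(
            f"model has {model.config.n_classes} outputs but the data has "
            f"{len(classes)} classes"
        )
    x_tr = np.ascontiguousarray(train_set.data, dtype=nn.DTYPE)
    x_va = np.ascontiguousarray(val_set.data, dtype=nn.DTYPE)

    weights = None
    if config.class_weighting:
        counts = np.bincount(y_tr, minlength=len(classes))
        w_class = counts.sum() / (len(classes) * np.maximum(counts, 1))
        weights = w_class[y_tr]

    rng = np.random.default_rng(config.seed)
    optimizer = nn.Adam(model.parameters(), lr=config.lr_init)
    history = TrainHistory()
    best_weights = model.get_weights()
    best_acc = -np.inf
    epochs_since_best = 0
    lr = config.lr_init

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(x_tr))
        losses, counts_seen = [], []
        for start in range(0, len(order), config.batch_size):
            idx = order[start:start + config.batch_size]
            optimizer.zero_grad()
            logits = model.forward(x_tr[idx])
            w = None if weights is None else weights[idx]
            loss, dlogits = nn.softmax_cross_entropy(logits, y_tr[idx], w)
            model.backward(dlogits)
            optimizer.step()
            losses.append(loss)
            counts_seen.append(len(idx))
        train_loss = float(np.average(losses, weights=counts_seen))
        val_loss, val_acc = evaluate_loss_acc(model, x_va, y_va)

        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.val_accuracy.append(val_acc)
        history.learning_rate.append(lr)

        if val_acc > best_acc:
            best_acc = val_acc
            best_weights = model.get_weights()
            history.best_epoch = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1

        lr = lr_plateau_step(lr, history.val_loss,
                             config.plateau_patience, config.lr_decay_factor)
        optimizer.lr = lr

        if epochs_since_best >= config.early_stop_patience:
            break

    history.best_val_accuracy = float(best_acc)
    model.set_weights(best_weights)
    return model, history
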
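"""Leave-one-subject-out (LOSO) evaluation machinery.

Each of the N subjects serves once as the held-out test set; the remaining
trials are split 80/20 (stratified by label) into training and validation.
Metrics are accuracy and macro-averaged F1, aggregated as mean +/- SD over
folds, with a confusion matrix summed over folds. Ablation sweeps rerun the
same folds for the full model and each single-branch variant; LDA and
linear-SVM baselines on channel-mean features share the identical splits.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from .model import VARIANTS, DBJNet, make_variant
from .preprocess import EpochSet
from .train import TrainConfig, _batch_logits, train_model

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TaskSpec:
    name: str
    kept_labels: tuple[int, ...]

    @property
    def label_map(self) -> dict[int, int]:
        return {lab: i for i, lab in enumerate(sorted(self.kept_labels))}

    @property
    def n_classes(self) -> int:
        return len(self.kept_labels)


#: label semantics: 1 = negative, 2 = neutral, 3 = positive
TASKS: dict[str, TaskSpec] = {
    "pos_neu_neg": TaskSpec("pos_neu_neg", (1, 2, 3)),
    "neg_pos": TaskSpec("neg_pos", (1, 3)),
    "neg_neu": TaskSpec("neg_neu", (1, 2)),
    "pos_neu": TaskSpec("pos_neu", (2, 3)),
}


def make_task(task_name: str, epoch_set: EpochSet) -> EpochSet:
    """Filter trials to the task's labels and remap them to contiguous
    class indices (0-based, ascending original label)."""
    if task_name not in TASKS:
        raise ValueError(f"unknown task {task_name!r}; choose from "
                         f"{sorted(TASKS)}")
    spec = TASKS[task_name]
    present = set(np.unique(epoch_set.labels).tolist())
    missing = set(spec.kept_labels) - present
    if missing:
        raise ValueError(
            f"task {task_name!r} needs labels {sorted(missing)} which are "
            "absent from the data"
        )
    mask = np.isin(epoch_set.labels, spec.kept_labels)
    subset = epoch_set.select(mask)
    lut = spec.label_map
    subset.labels = np.array([lut[y] for y in subset.labels])
    return subset


def loso_split(epoch_set: EpochSet, test_subject: str,
               val_fraction: float = 0.2, seed: int = 0
               ) -> tuple[EpochSet, EpochSet, EpochSet]:
    """Hold out all trials of ``test_subject``; split the rest 80/20 into
    train/validation, stratified by label."""
    subjects = epoch_set.subjects()
    if test_subject not in subjects:
        raise ValueError(f"unknown subject {test_subject!r}")
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects for LOSO")
    test_mask = epoch_set.subject_ids == test_subject
    test_set = epoch_set.select(test_mask)
    rest = epoch_set.select(~test_mask)
    idx = np.arange(len(rest))
    tr_idx, va_idx = train_test_split(
        idx, test_size=val_fraction, stratify=rest.labels,
        random_state=int(seed) % (2 ** 32),
    )
    return rest.select(tr_idx), rest.select(va_idx), test_set


def evaluate_model(model, test_set: EpochSet, n_classes: int | None = None
                   ) -> tuple[float, float, np.ndarray]:
    """Accuracy, macro-F1, and the confusion matrix (rows = true class)."""
    if len(test_set) == 0:
        raise ValueError("empty test set")
    y_true = test_set.labels
    if hasattr(model, "forward"):  # DBJNet
        n_classes = n_classes or model.config.n_classes
        logits = _batch_logits(model, np.asarray(test_set.data, np.float32))
        y_pred = logits.argmax(axis=1)
    else:  # sklearn-style estimator on channel-mean features
        y_pred = model.predict(channel_mean_features(test_set))
        if n_classes is None:
            n_classes = int(max(y_true.max(), y_pred.max())) + 1
    labels = list(range(n_classes))
    acc = accuracy_score(y_true, y_pred)
    f1 = f1_score(y_true, y_pred, labels=labels, average="macro",
                  zero_division=0)
    cm = confusion_matrix(y_true, y_pred, labels=labels)
    return float(acc), float(f1), cm


@dataclass
class FoldResult:
    test_subject: str
    accuracy: float
    f1: float
    n_test: int


@dataclass
class LosoReport:
    task: str
    variant: str
    folds: list[FoldResult]
    confusion: np.ndarray
    seed: int

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.folds])

    @property
    def fold_f1s(self) -> np.ndarray:
        return np.array([f.f1 for f in self.folds])

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def sd_accuracy(self) -> float:
        return float(self.fold_accuracies.std(ddof=1)) if len(self.folds) > 1 \
            else 0.0

    @property
    def mean_f1(self) -> float:
        return float(self.fold_f1s.mean())

    @property
    def sd_f1(self) -> float:
        return float(self.fold_f1s.std(ddof=1)) if len(self.folds) > 1 else 0.0

    def to_dict(self) -> dict:
        return {
            "task": self.task,
            "variant": self.variant,
            "seed": self.seed,
            "folds": [dataclasses.asdict(f) for f in self.folds],
            "confusion": self.confusion.tolist(),
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_f1": self.mean_f1,
            "sd_f1": self.sd_f1,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LosoReport":
        return cls(
            task=d["task"], variant=d["variant"], seed=d["seed"],
            folds=[FoldResult(**f) for f in d["folds"]],
            confusion=np.asarray(d["confusion"]),
        )


def _fold_seeds(master_seed: int, n_subjects: int) -> np.ndarray:
    """Deterministic per-fold (split, init, shuffle) seeds."""
    return np.random.SeedSequence(master_seed).generate_state(3 * n_subjects)


def run_loso(epoch_set: EpochSet, task: str, model_factory,
             train_config: TrainConfig = TrainConfig(),
             master_seed: int = 0) -> LosoReport:
    """Full LOSO sweep: for every subject, split, train a fresh model, and
    evaluate on the held-out subject.

    ``model_factory(n_classes, seed)`` must return an untrained model; for
    DBJNet use e.g. ``lambda k, s: DBJNet(make_variant("full", k), seed=s)``.
    """
    data = make_task(task, epoch_set)
    subjects = data.subjects()
    seeds = _fold_seeds(master_seed, len(subjects))
    n_classes = TASKS[task].n_classes
    folds: list[FoldResult] = []
    confusion = np.zeros((n_classes, n_classes), dtype=int)
    for i, subj in enumerate(subjects):
        split_seed, init_seed, shuffle_seed = (int(s) for s in
                                               seeds[3 * i:3 * i + 3])
        try:
            train, val, test = loso_split(data, subj, seed=split_seed)
            model = model_factory(n_classes, init_seed)
            fold_cfg = dataclasses.replace(train_config, seed=shuffle_seed)
            if hasattr(model, "forward"):
                model, _ = train_model(model, train, val, fold_cfg)
            else:
                x = channel_mean_features(train, val)
                y = np.concatenate([train.labels, val.labels])
                model.fit(x, y)
            acc, f1, cm = evaluate_model(model, test, n_classes)
        except Exception as exc:
            raise RuntimeError(
                f"LOSO fold for subject {subj!r} failed: {exc}"
            ) from exc
        folds.append(FoldResult(subj, acc, f1, len(test)))
        confusion += cm
    return LosoReport(task=task, variant=getattr(model_factory, "variant",
                                                 "custom"),
                      folds=folds, confusion=confusion, seed=master_seed)


def dbjnet_factory(variant: str = "full", **config_kwargs):
    """A model factory for run_loso building a DBJNet of the given variant."""
    def factory(n_classes: int, seed: int) -> DBJNet:
        cfg = make_variant(variant, n_classes=n_classes, **config_kwargs)
        return DBJNet(cfg, seed=seed)
    factory.variant = variant
    return factory


def run_ablation(epoch_set: EpochSet, tasks=("pos_neu_neg",),
                 train_config: TrainConfig = TrainConfig(),
                 master_seed: int = 0,
                 variants=VARIANTS) -> dict[tuple[str, str], LosoReport]:
    """LOSO per (variant, task) cell. Every variant reuses the same master
    seed, hence identical fold splits, for a controlled comparison."""
    out: dict[tuple[str, str], LosoReport] = {}
    for variant in variants:
        for task in tasks:
            out[(variant, task)] = run_loso(
                epoch_set, task, dbjnet_factory(variant),
                train_config, master_seed,
            )
    return out


def channel_mean_features(*epoch_sets: EpochSet) -> np.ndarray:
    """Per-trial per-channel temporal mean: (n_trials, n_channels)."""
    return np.concatenate([es.data.mean(axis=2) for es in epoch_sets], axis=0)


class _ShrinkageLDA:
    """LDA that falls back to shrinkage if the covariance is singular."""

    variant = "lda"

    def __init__(self):
        self._est = None

    def fit(self, x, y):
        est = LinearDiscriminantAnalysis(solver="svd")
        try:
            with np.errstate(all="raise"):
                est.fit(x, y)
        except (np.linalg.LinAlgError, FloatingPointError):
            logger.warning("singular within-class covariance; refitting LDA "
                           "with automatic shrinkage")
            est = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
            est.fit(x, y)
        self._est = est
        return self

    def predict(self, x):
        return self._est.predict(x)


def baseline_factory(method: str):
    if method == "lda":
        def factory(n_classes, seed):
            return _ShrinkageLDA()
    elif method == "linear_svm":
        def factory(n_classes, seed):
            return SVC(kernel="linear", random_state=int(seed) % (2 ** 32))
    else:
        raise ValueError(f"unknown baseline {method!r}")
    factory.variant = method
    return factory


def baseline_classify(epoch_set: EpochSet, task: str, method: str,
                      master_seed: int = 0) -> LosoReport:
    """LOSO for a classical baseline (LDA or linear SVM) on channel-mean
    features, under the same fold splits as the network (the baselines have
    no validation stage, so train and validation trials are pooled)."""
    return run_loso(epoch_set, task, baseline_factory(method),
                    TrainConfig(), master_seed)


def plot_confusion(report: LosoReport, path, class_names=None) -> None:
    """Render the summed confusion matrix as a heat map image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = report.confusion
    n = cm.shape[0]
    names = class_names or [str(i) for i in range(n)]
    fig, ax = plt.subplots(figsize=(4, 3.5))
    im = ax.imshow(cm, cmap="Blues")
    for i in range(n):
        for j in range(n):
            ax.text(j, i, str(cm[i, j]), ha="center", va="center",
                    color="black" if cm[i, j] < cm.max() / 2 else "white")
    ax.set_xticks(range(n), names)
    ax.set_yticks(range(n), names)
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(f"{report.task} ({report.variant})")
    fig.colorbar(im)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
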
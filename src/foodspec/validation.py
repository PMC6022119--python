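"""Evaluation protocols: repeated k-fold CV, inter-session testing, baselines.

Two protocols are provided.  *Repeated cross-validation* estimates
within-session accuracy: stratified k-fold partitions are redrawn for each
repeat, a model is fitted per training fold, and accuracy is recorded per
fold, giving ``repeats × k`` values per component count (their mean ± 2 SD
is the conventional error bar).  *Inter-session evaluation* trains on one
acquisition session and tests on another recorded under different ambient
conditions — the guard against a model that has merely memorised
session-specific background.

Both report accuracy as a function of the number of PLS components, against
a ZeroR baseline (always guess the majority class).

Preprocessing stages are all per-row (no statistic pooled across rows), so
applying them once up front leaks nothing between folds; the column
centering that *is* data-dependent happens inside ``fit_simpls`` on the
training fold only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .simpls import ClassEncoding, fit_plsda, predict_class
from .spectra import SampleMeta, SpectraSet

__all__ = [
    "EvalConfig",
    "AccuracyCurve",
    "ConfusionMatrix",
    "task_labels",
    "zeror",
    "repeated_cv",
    "intersession_eval",
    "confusion",
    "select_components",
]

#: Task selector: "type", "organic", "ova:<label>", or a callable on SampleMeta.
TaskSelector = str | Callable[[SampleMeta], str]


@dataclass(frozen=True)
class EvalConfig:
    k_folds: int = 10
    repeats: int = 10
    components_range: tuple[int, ...] = tuple(range(1, 16))
    seed: int = 0
    fold_unit: str = "sample"  # or "specimen": keep all rows of an apple on one side

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not self.components_range:
            raise ValueError("components_range must be non-empty")
        if any(a < 1 for a in self.components_range):
            raise ValueError("component counts must be >= 1")
        if self.fold_unit not in ("sample", "specimen"):
            raise ValueError(f"fold_unit must be 'sample' or 'specimen', got {self.fold_unit!r}")


@dataclass
class AccuracyCurve:
    """Accuracy (percent) versus number of PLS components.

    ``sd_accuracy`` is empty for single-evaluation protocols; ``records``
    holds the per-fold accuracies behind the means, for tidy-CSV export.
    """

    components: list[int]
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    n_evaluations: int
    records: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.mean_accuracy = np.asarray(self.mean_accuracy, dtype=float)
        self.sd_accuracy = np.asarray(self.sd_accuracy, dtype=float)
        if len(self.components) != self.mean_accuracy.size:
            raise ValueError("components and mean_accuracy lengths differ")
        if self.sd_accuracy.size not in (0, self.mean_accuracy.size):
            raise ValueError("sd_accuracy must be empty or match mean_accuracy")
        if self.mean_accuracy.size and not (
            np.all(self.mean_accuracy >= 0) and np.all(self.mean_accuracy <= 100)
        ):
            raise ValueError("accuracies must lie in [0, 100]")

    def accuracy_at(self, a: int) -> float:
        return float(self.mean_accuracy[self.components.index(a)])

    def to_frame(self) -> pd.DataFrame:
        sd = self.sd_accuracy if self.sd_accuracy.size else np.full(len(self.components), np.nan)
        return pd.DataFrame(
            {"n_components": self.components, "mean": self.mean_accuracy, "sd": sd}
        )


@dataclass
class ConfusionMatrix:
    """Counts and row-normalised percentages; rows are truth, columns prediction."""

    classes: list[str]
    counts: np.ndarray
    row_percents: np.ndarray

    def to_frame(self, percents: bool = True) -> pd.DataFrame:
        data = self.row_percents if percents else self.counts
        return pd.DataFrame(data, index=self.classes, columns=self.classes)


def task_labels(metas: Sequence[SampleMeta], task: TaskSelector) -> list[str]:
    """Resolve a task selector to one class label per row."""
    if callable(task):
        return [task(m) for m in metas]
    if task == "type":
        return [m.type_label for m in metas]
    if task == "organic":
        return ["organic" if m.organic else "non-organic" for m in metas]
    if task.startswith("ova:"):
        target = task[4:]
        return [m.type_label if m.type_label == target else f"not {target}" for m in metas]
    raise ValueError(f"unknown task {task!r}")


def task_encoding(labels: Sequence[str], task: TaskSelector) -> ClassEncoding:
    """Deterministic class order: target first for one-vs-all, else sorted."""
    if isinstance(task, str) and task.startswith("ova:"):
        target = task[4:]
        return ClassEncoding((target, f"not {target}"))
    return ClassEncoding.from_labels(labels)


def zeror(labels: Sequence[str]) -> float:
    """Majority-class accuracy in percent: the baseline any model must beat."""
    if len(labels) == 0:
        raise ValueError("empty label list")
    (_, top_count), = Counter(labels).most_common(1)
    return 100.0 * top_count / len(labels)


def _accuracy(true: Sequence[str], pred: Sequence[str]) -> float:
    return 100.0 * float(np.mean([t == p for t, p in zip(true, pred)]))


def _splits(labels: list[str], metas: Sequence[SampleMeta], cfg: EvalConfig, seed: int):
    y = np.asarray(labels)
    X_dummy = np.zeros((len(y), 1))
    if cfg.fold_unit == "specimen":
        groups = np.asarray([m.specimen_id for m in metas])
        if len(set(groups)) < cfg.k_folds:
            raise ValueError(
                f"{len(set(groups))} specimens cannot fill {cfg.k_folds} folds"
            )
        splitter = StratifiedGroupKFold(n_splits=cfg.k_folds, shuffle=True, random_state=seed)
        return list(splitter.split(X_dummy, y, groups=groups))
    splitter = StratifiedKFold(n_splits=cfg.k_folds, shuffle=True, random_state=seed)
    return list(splitter.split(X_dummy, y))


def repeated_cv(s: SpectraSet, cfg: EvalConfig, task: TaskSelector = "type") -> AccuracyCurve:
    """Repeated stratified k-fold cross-validation over a component range.

    For each repeat a fresh stratified partition is drawn (seeded by
    ``cfg.seed + repeat``); one model per training fold is fitted at the
    largest requested component count and evaluated truncated to each
    smaller count, which is numerically identical to refitting at each count.
    Mean and SD are taken over the ``repeats × k_folds`` per-fold accuracies.
    """
    labels = task_labels(s.metas, task)
    counts = Counter(labels)
    if min(counts.values()) < cfg.k_folds:
        raise ValueError(
            f"smallest class has {min(counts.values())} members; cannot stratify "
            f"into {cfg.k_folds} folds"
        )
    encoding = task_encoding(labels, task)
    comps = sorted(cfg.components_range)
    a_max = comps[-1]

    rows = []
    for rep in range(cfg.repeats):
        for fold_i, (train_idx, test_idx) in enumerate(
            _splits(labels, s.metas, cfg, cfg.seed + rep)
        ):
            train = s.subset(train_idx)
            model = fit_plsda(train, [labels[i] for i in train_idx], a_max, encoding=encoding)
            X_test = s.matrix[test_idx]
            true = [labels[i] for i in test_idx]
            for a in comps:
                pred = predict_class(model, X_test, n_components=a)
                rows.append((a, rep, fold_i, _accuracy(true, pred)))

    records = pd.DataFrame(rows, columns=["n_components", "repeat", "fold", "accuracy"])
    grouped = records.groupby("n_components")["accuracy"]
    mean = grouped.mean().reindex(comps).to_numpy()
    sd = grouped.std(ddof=1).reindex(comps).fillna(0.0).to_numpy()
    return AccuracyCurve(
        components=comps,
        mean_accuracy=mean,
        sd_accuracy=sd,
        n_evaluations=cfg.repeats * cfg.k_folds,
        records=records,
    )


def intersession_eval(
    train: SpectraSet,
    test: SpectraSet,
    cfg: EvalConfig,
    task: TaskSelector = "type",
) -> AccuracyCurve:
    """Train on one full session, test on another; one accuracy per component count.

    Sessions must be disjoint (shared session ids would mean test rows were
    recorded alongside training rows, defeating the purpose of the protocol).
    """
    if train.grid != test.grid:
        raise ValueError("train and test sets must share a wavelength grid")
    overlap = train.session_ids() & test.session_ids()
    if overlap:
        raise ValueError(f"train and test share session ids {sorted(overlap)}")

    train_labels = task_labels(train.metas, task)
    test_labels = task_labels(test.metas, task)
    encoding = task_encoding(train_labels, task)
    comps = sorted(cfg.components_range)
    model = fit_plsda(train, train_labels, comps[-1], encoding=encoding)

    acc = [
        _accuracy(test_labels, predict_class(model, test.matrix, n_components=a))
        for a in comps
    ]
    return AccuracyCurve(
        components=comps,
        mean_accuracy=np.array(acc),
        sd_accuracy=np.array([]),
        n_evaluations=1,
    )


def confusion(
    true: Sequence[str], predicted: Sequence[str], classes: Sequence[str]
) -> ConfusionMatrix:
    """Confusion matrix in the conventional orientation (rows truth, columns prediction)."""
    if len(true) != len(predicted):
        raise ValueError("true and predicted must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(true, predicted):
        if t not in index or p not in index:
            raise ValueError(f"label outside class list: {t!r} / {p!r}")
        counts[index[t], index[p]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        percents = np.where(row_sums > 0, 100.0 * counts / row_sums, 0.0)
    return ConfusionMatrix(classes=list(classes), counts=counts, row_percents=percents)


def select_components(curve: AccuracyCurve) -> int:
    """Component count with the highest mean accuracy; ties favour fewer components."""
    if not curve.components:
        raise ValueError("empty accuracy curve")
    order = np.argsort(curve.components)
    comps = np.asarray(curve.components)[order]
    accs = curve.mean_accuracy[order]
    return int(comps[int(np.argmax(accs))])
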
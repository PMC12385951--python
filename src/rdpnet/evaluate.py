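"""Cross-validation protocol, metrics and confidence intervals.

Stratified k-fold cross-validation over fixed-length segments (with an
optional record-grouped mode in which every segment of a recording stays
in the same fold — leakage-safe, subject to the caveat that the corpus
itself is not subject-annotated).  Per fold: the training portion is
augmented, the model trained and its training-set-optimum checkpoint
evaluated on untouched test segments.  Fold metrics are aggregated into
means, sample standard deviations and t-based 95% confidence intervals,
``mean ± t(1-a/2, k-1) * s / sqrt(k)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .io_bonn import EEGRecord, TaskSpec
from .model import ModelConfig, RDPNet, build_model, count_parameters
from .preprocess import (AugmentConfig, LabeledSegment, augment_segments,
                         segment_record, segments_to_arrays)
from .train import TrainConfig, TrainHistory, predict, train_model

METRICS = ("accuracy", "precision", "recall", "f1", "weighted_f1")


class SplitError(ValueError):
    """A class has too few members for the requested number of folds."""


@dataclass
class FoldResult:
    """Metrics of one fold, all in percent; macro averaging for
    precision/recall/F1, plus the class-frequency-weighted F1."""

    fold: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    weighted_f1: float
    confusion: np.ndarray

    def metric(self, name: str) -> float:
        return float(getattr(self, name))


@dataclass
class CVReport:
    """Aggregate of a k-fold run: per-fold results, mean/std/CI per
    metric, the summed confusion matrix and per-fold training histories."""

    task: str
    k: int
    folds: list[FoldResult]
    mean: dict[str, float]
    std: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    confusion: np.ndarray
    histories: list[TrainHistory] = field(default_factory=list)
    n_parameters: int = 0

    def to_dict(self) -> dict:
        return {
            "task": self.task, "k": self.k,
            "n_parameters": self.n_parameters,
            "folds": [{m: f.metric(m) for m in METRICS} | {"fold": f.fold}
                      for f in self.folds],
            "mean": self.mean, "std": self.std,
            "ci95": {m: list(v) for m, v in self.ci95.items()},
            "confusion": self.confusion.tolist(),
        }

    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))

    def fold_table(self) -> pd.DataFrame:
        return pd.DataFrame([{m: f.metric(m) for m in METRICS}
                             | {"fold": f.fold} for f in self.folds])


def stratified_kfold(labels: np.ndarray, k: int, seed: int = 0,
                     groups: np.ndarray | None = None,
                     ) -> list[tuple[np.ndarray, np.ndarray]]:
    """k stratified (train, test) index partitions.

    With ``groups``, all items of a group (e.g. segments of one record)
    share a fold.  Per-class counts across folds differ by at most one in
    the ungrouped case.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise SplitError("k must be >= 2")
    if groups is None:
        counts = np.bincount(labels)
        low = counts[counts > 0].min()
        if low < k:
            raise SplitError(f"smallest class has {low} items, fewer than "
                             f"k={k} folds")
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return [(tr, te) for tr, te in
                splitter.split(np.zeros(len(labels)), labels)]
    groups = np.asarray(groups)
    for cls in np.unique(labels):
        if len(np.unique(groups[labels == cls])) < k:
            raise SplitError(f"class {cls} has fewer than k={k} groups")
    splitter = StratifiedGroupKFold(n_splits=k, shuffle=True,
                                    random_state=seed)
    return [(tr, te) for tr, te in
            splitter.split(np.zeros(len(labels)), labels, groups)]


def compute_metrics(predictions: np.ndarray, labels: np.ndarray,
                    n_classes: int, fold: int = 0) -> FoldResult:
    """Accuracy, macro precision/recall/F1 and weighted F1, in percent."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.size == 0 or predictions.shape != labels.shape:
        raise ValueError("predictions and labels must be equal-length and "
                         "non-empty")
    classes = np.arange(n_classes)
    acc = float((predictions == labels).mean()) * 100.0
    prec, rec, f1, _ = precision_recall_fscore_support(
        labels, predictions, labels=classes, average="macro",
        zero_division=0)
    _, _, wf1, _ = precision_recall_fscore_support(
        labels, predictions, labels=classes, average="weighted",
        zero_division=0)
    cm = _sk_confusion(labels, predictions, labels=classes)
    return FoldResult(fold=fold, accuracy=acc, precision=prec * 100,
                      recall=rec * 100, f1=f1 * 100,
                      weighted_f1=wf1 * 100, confusion=cm)


def t_confidence_interval(values: list[float] | np.ndarray,
                          level: float = 0.95,
                          truncate_at: float | None = None,
                          ) -> tuple[float, float]:
    """t-distribution confidence interval of the mean of fold metrics.

    ``truncate_at`` clips the upper bound (e.g. 100 for percentages) —
    intended for display; stored report values are untruncated.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 values for a confidence interval")
    k = values.size
    mean = values.mean()
    s = values.std(ddof=1)
    tq = stats.t.ppf(0.5 + level / 2.0, df=k - 1)
    half = tq * s / np.sqrt(k)
    lo, hi = mean - half, mean + half
    if truncate_at is not None:
        hi = min(hi, truncate_at)
    return float(lo), float(hi)


def _aggregate(folds: list[FoldResult], task: str, k: int,
               histories: list[TrainHistory],
               n_parameters: int) -> CVReport:
    mean, std, ci = {}, {}, {}
    for m in METRICS:
        vals = [f.metric(m) for f in folds]
        mean[m] = float(np.mean(vals))
        std[m] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        ci[m] = t_confidence_interval(vals) if len(vals) > 1 \
            else (mean[m], mean[m])
    confusion = np.sum([f.confusion for f in folds], axis=0)
    return CVReport(task=task, k=k, folds=folds, mean=mean, std=std,
                    ci95=ci, confusion=confusion, histories=histories,
                    n_parameters=n_parameters)


def run_cv(records: list[EEGRecord], task: TaskSpec, model_cfg: ModelConfig,
           train_cfg: TrainConfig, k: int = 10, seed: int = 0,
           window: int = 512, augment: AugmentConfig | None = None,
           group_by_record: bool = False) -> CVReport:
    """The full cross-validation protocol on a set of records.

    Records outside the task's sets are dropped; all remaining records
    are segmented, split into stratified folds (segment-level by
    default), the training portion of each fold augmented, a fresh model
    trained per fold and evaluated on the fold's untouched original
    segments.
    """
    augment = augment or AugmentConfig(seed=seed)
    if model_cfg.n_classes != task.n_classes:
        import dataclasses
        model_cfg = dataclasses.replace(model_cfg, n_classes=task.n_classes)
    segments: list[LabeledSegment] = []
    for record in records:
        if record.set_label not in task.class_map:
            continue
        segments.extend(segment_record(
            record, window, label=task.class_map[record.set_label]))
    if not segments:
        raise ValueError("no records match the task's sets")
    labels = np.array([s.label for s in segments])
    groups = np.array([s.origin_id for s in segments]) if group_by_record \
        else None
    folds = stratified_kfold(labels, k=k, seed=seed, groups=groups)
    results: list[FoldResult] = []
    histories: list[TrainHistory] = []
    n_params = 0
    for fold_idx, (train_idx, test_idx) in enumerate(folds):
        train_segs = augment_segments(
            [segments[i] for i in train_idx],
            AugmentConfig(alpha=augment.alpha,
                          copies_per_original=augment.copies_per_original,
                          seed=augment.seed + fold_idx))
        test_segs = [segments[i] for i in test_idx]
        model = build_model(model_cfg, seed=seed * 1000 + fold_idx)
        n_params = count_parameters(model)
        model, history = train_model(
            model, train_segs,
            TrainConfig(**{**train_cfg.to_dict(),
                           "seed": train_cfg.seed * 1000 + fold_idx}))
        preds = predict(model, test_segs)
        y_test = np.array([s.label for s in test_segs])
        results.append(compute_metrics(preds, y_test, task.n_classes,
                                       fold=fold_idx))
        histories.append(history)
    return _aggregate(results, task.name, k, histories, n_params)


def export_embeddings(model: RDPNet, segments: list[LabeledSegment],
                      stage: str, batch_size: int = 256,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment feature vectors for external 2-D projection.

    ``stage`` is ``rcm`` or ``dcpm`` (channel-wise max-pooled feature
    maps, width 128) or ``fused`` (the fusion vector, width 512).
    Returns (features, labels), one row per segment.
    """
    x, y = segments_to_arrays(segments)
    model.eval()
    chunks = []
    for start in range(0, x.shape[0], batch_size):
        model.forward(x[start:start + batch_size])
        chunks.append(model.features(stage))
    return np.concatenate(chunks, axis=0), y


def embeddings_to_csv(features: np.ndarray, labels: np.ndarray,
                      path: str | Path) -> None:
    df = pd.DataFrame(features,
                      columns=[f"f{i}" for i in range(features.shape[1])])
    df.insert(0, "label", labels)
    df.to_csv(path, index=False)
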
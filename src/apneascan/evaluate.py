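"""Per-segment metrics, per-recording AHI diagnosis and cross-validation.

Per-segment: confusion counts with apnea as the positive class, specificity
TN/(TN+FP), sensitivity TP/(TP+FN), accuracy, ROC AUC. Per-recording: the
apnea-hypopnea index AHI = 60/T * (apnea minutes) over T labeled minutes; a
recording with AHI > 5 is diagnosed as sleep apnea, and the estimated-vs-true
AHI Pearson correlation summarizes severity agreement. Cross-validation folds
partition at the recording level so no recording contributes minutes to both
train and test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .ecg_io import APNEA

__all__ = [
    "ConfusionCounts",
    "SegmentMetrics",
    "RecordingDiagnosis",
    "segment_metrics",
    "roc_auc",
    "compute_ahi",
    "diagnose_recordings",
    "ten_fold_cv",
    "CVResult",
]

AHI_DIAGNOSIS_THRESHOLD = 5.0


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, y_true: Sequence[str], y_pred: Sequence[str], positive: str = APNEA):
        if len(y_true) != len(y_pred):
            raise ValueError("label sequences must have equal length")
        tp = sum(t == positive and p == positive for t, p in zip(y_true, y_pred))
        tn = sum(t != positive and p != positive for t, p in zip(y_true, y_pred))
        fp = sum(t != positive and p == positive for t, p in zip(y_true, y_pred))
        fn = sum(t == positive and p != positive for t, p in zip(y_true, y_pred))
        return cls(tp=tp, tn=tn, fp=fp, fn=fn)


class SegmentMetrics(NamedTuple):
    specificity: float
    sensitivity: float
    accuracy: float


def segment_metrics(counts: ConfusionCounts) -> SegmentMetrics:
    """Specificity, sensitivity and accuracy; NaN flags a zero denominator."""
    sp = counts.tn / (counts.tn + counts.fp) if counts.tn + counts.fp else math.nan
    sn = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else math.nan
    acc = (counts.tp + counts.tn) / counts.total if counts.total else math.nan
    return SegmentMetrics(specificity=sp, sensitivity=sn, accuracy=acc)


def roc_auc(y_true: Sequence[str], scores: Sequence[float], positive: str = APNEA) -> float:
    """Area under the ROC curve of a continuous apnea score.

    Rank-based (Mann-Whitney) AUC with tie averaging; requires both classes.
    """
    y = np.asarray([1 if t == positive else 0 for t in y_true])
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def compute_ahi(predicted_labels: Sequence[str], t_minutes: int | None = None) -> float:
    """AHI = 60/T * (number of apnea minutes); events per hour."""
    t = len(predicted_labels) if t_minutes is None else t_minutes
    if t < 1:
        raise ValueError("T must be >= 1 minute")
    n = sum(1 for l in predicted_labels if l == APNEA)
    return 60.0 / t * n


@dataclass(frozen=True)
class RecordingDiagnosis:
    """Estimated and true AHI for one recording, with the AHI>5 diagnosis."""

    record_id: str
    estimated_ahi: float
    true_ahi: float

    def __post_init__(self) -> None:
        if self.estimated_ahi < 0 or self.true_ahi < 0:
            raise ValueError("AHI must be non-negative")

    @property
    def predicted_sa(self) -> bool:
        return self.estimated_ahi > AHI_DIAGNOSIS_THRESHOLD

    @property
    def truth_sa(self) -> bool:
        return self.true_ahi > AHI_DIAGNOSIS_THRESHOLD


def diagnose_recordings(diags: Sequence[RecordingDiagnosis]) -> dict:
    """Recording-level confusion, metrics and AHI Pearson correlation.

    SA (AHI > 5) is the positive class. AUC treats the estimated AHI as the
    continuous score; it and the Pearson r are NaN when undefined (one truth
    class only / zero AHI variance).
    """
    if len(diags) < 1:
        raise ValueError("need at least one recording")
    y_true = [APNEA if d.truth_sa else "N" for d in diags]
    y_pred = [APNEA if d.predicted_sa else "N" for d in diags]
    counts = ConfusionCounts.from_labels(y_true, y_pred)
    metrics = segment_metrics(counts)
    est = np.array([d.estimated_ahi for d in diags])
    tru = np.array([d.true_ahi for d in diags])
    try:
        auc = roc_auc(y_true, est)
    except ValueError:
        auc = math.nan
    if len(diags) >= 2 and np.std(est) > 0 and np.std(tru) > 0:
        r = float(stats.pearsonr(est, tru).statistic)
    else:
        r = math.nan
    return {
        "counts": counts,
        "accuracy": metrics.accuracy,
        "sensitivity": metrics.sensitivity,
        "specificity": metrics.specificity,
        "auc": auc,
        "pearson_r": r,
    }


@dataclass
class CVResult:
    fold_record_ids: list[list[str]]
    accuracies: list[float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0


def ten_fold_cv(
    recordings: Sequence,
    pipeline: Callable[[Sequence, Sequence], tuple[Sequence[str], Sequence[str]]],
    seed: int = 0,
    n_folds: int = 10,
) -> CVResult:
    """Recording-level k-fold cross-validation of an end-to-end pipeline.

    ``pipeline(train_recordings, test_recordings)`` must return per-segment
    ``(y_true, y_pred)`` for the test recordings. Recordings are shuffled with
    ``seed`` and partitioned so each appears in exactly one test fold.
    """
    if len(recordings) < n_folds:
        raise ValueError(f"need >= {n_folds} recordings for {n_folds}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(recordings))
    folds = np.array_split(order, n_folds)
    fold_ids: list[list[str]] = []
    accs: list[float] = []
    for fold in folds:
        test = [recordings[i] for i in fold]
        train = [recordings[i] for i in order if i not in set(fold)]
        y_true, y_pred = pipeline(train, test)
        counts = ConfusionCounts.from_labels(y_true, y_pred)
        accs.append(segment_metrics(counts).accuracy)
        fold_ids.append([_record_id(r) for r in test])
    return CVResult(fold_record_ids=fold_ids, accuracies=accs)


def _record_id(rec) -> str:
    for attr in ("record_id",):
        if hasattr(rec, attr):
            return getattr(rec, attr)
    if hasattr(rec, "recording"):
        return rec.recording.record_id
    return str(rec)
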
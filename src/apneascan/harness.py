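"""End-to-end experiment drivers: cohort -> windows -> classifier -> metrics.

These helpers wire the stage modules together the way the evaluation design
requires: preprocessing is computed once per recording, train/test splits and
cross-validation folds are formed at the recording level, the CNN consumes
window tensors (standardized per channel with training-set statistics) while
the baselines consume min-max-normalized HRV feature vectors, and predictions
are rolled up into per-segment metrics and per-recording AHI diagnoses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import model as mdl
from .baselines import BaselineConfig, fit_baseline, predict_baseline
from .ecg_io import APNEA
from .evaluate import (
    ConfusionCounts,
    RecordingDiagnosis,
    compute_ahi,
    diagnose_recordings,
    roc_auc,
    segment_metrics,
)
from .features import extract_feature_vector
from .preprocess import (
    WindowTensor,
    build_dataset,
    compute_rr_and_amplitude,
    detect_r_peaks,
    median_filter_rr,
)
from .simulate import SimRecording

__all__ = [
    "PreparedRecording",
    "prepare_recording",
    "prepare_cohort",
    "ExperimentResult",
    "run_cnn_experiment",
    "run_baseline_experiment",
    "make_cnn_pipeline",
    "make_baseline_pipeline",
    "reference_cohort_experiment",
]


@dataclass
class PreparedRecording:
    """Windows and feature vectors for one recording, computed once."""

    record_id: str
    windows: list[WindowTensor]
    features: np.ndarray  # (n_minutes, 18)
    true_labels: tuple[str, ...]
    true_ahi: float


def prepare_recording(sim: SimRecording) -> PreparedRecording:
    """Run the preprocessing pipeline and feature extraction on one recording."""
    rec, labels = sim.recording, sim.labels
    peaks = detect_r_peaks(rec)
    rr = median_filter_rr(compute_rr_and_amplitude(peaks))
    windows = build_dataset(rec, labels)
    feats = np.stack([extract_feature_vector(w, rr) for w in windows])
    return PreparedRecording(
        record_id=rec.record_id,
        windows=windows,
        features=feats,
        true_labels=labels.labels[: len(windows)],
        true_ahi=compute_ahi(labels.labels),
    )


def prepare_cohort(cohort: Sequence[SimRecording]) -> dict[str, PreparedRecording]:
    return {sim.record_id: prepare_recording(sim) for sim in cohort}


@dataclass
class ExperimentResult:
    """Per-segment and per-recording outcomes of one train/test split."""

    y_true: tuple[str, ...]
    y_pred: tuple[str, ...]
    scores: np.ndarray
    diagnoses: list[RecordingDiagnosis]
    history: list[float] | None = None

    @property
    def segment_report(self) -> dict:
        counts = ConfusionCounts.from_labels(self.y_true, self.y_pred)
        m = segment_metrics(counts)
        report = {"counts": counts, **m._asdict()}
        try:
            report["auc"] = roc_auc(self.y_true, self.scores)
        except ValueError:
            report["auc"] = float("nan")
        return report

    @property
    def recording_report(self) -> dict:
        return diagnose_recordings(self.diagnoses)

    @property
    def majority_rate(self) -> float:
        n_apnea = sum(1 for l in self.y_true if l == APNEA)
        return max(n_apnea, len(self.y_true) - n_apnea) / len(self.y_true)


def _collect(prepared: dict[str, PreparedRecording], ids: Sequence[str]) -> list[PreparedRecording]:
    missing = [i for i in ids if i not in prepared]
    if missing:
        raise KeyError(f"unknown record ids {missing}")
    return [prepared[i] for i in ids]


def _channel_stats(windows: Sequence[WindowTensor]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([w.channels for w in windows])
    mean = x.mean(axis=(0, 1))
    sd = x.std(axis=(0, 1))
    return mean, np.where(sd > 0, sd, 1.0)


def _standardize(windows: Sequence[WindowTensor], mean: np.ndarray, sd: np.ndarray) -> list[WindowTensor]:
    out = []
    for w in windows:
        out.append(
            WindowTensor(
                record_id=w.record_id,
                minute_index=w.minute_index,
                grid=w.grid,
                rr=(w.rr - mean[0]) / sd[0],
                ampl=(w.ampl - mean[1]) / sd[1],
                label=w.label,
            )
        )
    return out


def _finish(
    prepared_test: list[PreparedRecording],
    pred_labels: Sequence[str],
    scores: np.ndarray,
    history: list[float] | None,
) -> ExperimentResult:
    y_true = tuple(l for p in prepared_test for l in p.true_labels)
    diagnoses = []
    offset = 0
    for p in prepared_test:
        n = len(p.true_labels)
        est = compute_ahi(pred_labels[offset : offset + n])
        diagnoses.append(
            RecordingDiagnosis(record_id=p.record_id, estimated_ahi=est, true_ahi=p.true_ahi)
        )
        offset += n
    return ExperimentResult(
        y_true=y_true,
        y_pred=tuple(pred_labels),
        scores=np.asarray(scores, dtype=float),
        diagnoses=diagnoses,
        history=history,
    )


def run_cnn_experiment(
    prepared: dict[str, PreparedRecording],
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    train_cfg: mdl.TrainConfig | None = None,
    spec: mdl.ModelSpec | None = None,
) -> ExperimentResult:
    """Train the modified LeNet-5 on the training recordings, score the rest."""
    train_cfg = train_cfg or mdl.TrainConfig(max_epochs=30)
    spec = spec or mdl.modified_lenet5()
    train_rec = _collect(prepared, train_ids)
    test_rec = _collect(prepared, test_ids)
    train_windows = [w for p in train_rec for w in p.windows]
    mean, sd = _channel_stats(train_windows)
    net = mdl.build_model(spec, seed=train_cfg.seed)
    net, history = mdl.train(net, _standardize(train_windows, mean, sd), train_cfg)
    test_windows = _standardize([w for p in test_rec for w in p.windows], mean, sd)
    preds = mdl.predict_proba(net, test_windows)
    return _finish(test_rec, preds.labels, preds.proba_apnea, history)


def run_baseline_experiment(
    prepared: dict[str, PreparedRecording],
    train_ids: Sequence[str],
    test_ids: Sequence[str],
    cfg: BaselineConfig,
) -> ExperimentResult:
    """Fit one feature-engineering baseline on min-max-normalized features."""
    from .features import minmax_fit_transform

    train_rec = _collect(prepared, train_ids)
    test_rec = _collect(prepared, test_ids)
    x_train = np.concatenate([p.features for p in train_rec])
    y_train = [l for p in train_rec for l in p.true_labels]
    x_test = np.concatenate([p.features for p in test_rec])
    x_train_n, x_test_n, _ = minmax_fit_transform(x_train, x_test)
    fitted = fit_baseline(cfg, x_train_n, y_train)
    labels, scores = predict_baseline(fitted, x_test_n)
    return _finish(test_rec, labels, scores, None)


def reference_cohort_experiment(
    seed: int = 1,
    n_records: int = 20,
    duration_min: int = 60,
    max_epochs: int = 30,
    baselines: Sequence[str] = ("svm", "lr", "knn", "mlp"),
) -> dict:
    """The package's standard synthetic benchmark, end to end.

    Simulates a cohort with a strong apnea signature (half the recordings
    sleep-apneic, half normal), splits it at the recording level (every third
    recording held out), trains the modified LeNet-5 on the training
    recordings and evaluates per-segment and per-recording performance on the
    held-out ones; each requested feature baseline runs through the identical
    split. Returns a flat summary dict of the measured quantities.
    """
    from .simulate import SimConfig, simulate_cohort

    cohort = simulate_cohort(
        n_records, (0.0, 0.5, 0.5), SimConfig(duration_min=duration_min), seed=seed
    )
    prepared = prepare_cohort(cohort)
    ids = [c.record_id for c in cohort]
    test_ids = ids[1::3]  # every third recording, covering both classes
    train_ids = [i for i in ids if i not in set(test_ids)]
    cfg = mdl.TrainConfig(max_epochs=max_epochs, seed=seed + 1)
    res = run_cnn_experiment(prepared, train_ids, test_ids, cfg)
    seg = res.segment_report
    rec = res.recording_report
    summary = {
        "n_test_segments": len(res.y_true),
        "n_test_recordings": len(res.diagnoses),
        "majority_class_rate": res.majority_rate,
        "cnn_segment_accuracy": seg["accuracy"],
        "cnn_segment_sensitivity": seg["sensitivity"],
        "cnn_segment_specificity": seg["specificity"],
        "cnn_segment_auc": seg["auc"],
        "cnn_recording_accuracy": rec["accuracy"],
        "cnn_ahi_pearson_r": rec["pearson_r"],
    }
    for name in baselines:
        bres = run_baseline_experiment(
            prepared, train_ids, test_ids, BaselineConfig(name=name, seed=seed + 2)
        )
        summary[f"{name}_segment_accuracy"] = bres.segment_report["accuracy"]
        summary[f"{name}_segment_auc"] = bres.segment_report["auc"]
    return summary


def make_cnn_pipeline(prepared: dict[str, PreparedRecording], train_cfg: mdl.TrainConfig | None = None):
    """Adapt the CNN experiment to the cross-validation pipeline contract."""

    def pipeline(train_recs, test_recs):
        res = run_cnn_experiment(
            prepared,
            [r.record_id for r in train_recs],
            [r.record_id for r in test_recs],
            train_cfg=train_cfg,
        )
        return res.y_true, res.y_pred

    return pipeline


def make_baseline_pipeline(prepared: dict[str, PreparedRecording], cfg: BaselineConfig):
    def pipeline(train_recs, test_recs):
        res = run_baseline_experiment(
            prepared,
            [r.record_id for r in train_recs],
            [r.record_id for r in test_recs],
            cfg,
        )
        return res.y_true, res.y_pred

    return pipeline
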
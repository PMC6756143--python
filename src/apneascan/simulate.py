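"""Synthetic single-lead apnea-ECG cohorts with ground truth.

The generator emulates the two physiological correlates the RR/amplitude
pipeline is built to capture: during apnea minutes the instantaneous heart
rate carries a cyclic bradycardia–tachycardia swing with a period of tens of
seconds, and R-peak amplitudes are modulated at the same respiratory-effort
cycle. Beats are placed by integrating the instantaneous heart rate, rendered
as a fixed narrow biphasic QRS-like template on Gaussian noise, and emitted
with per-minute labels, event-interval annotations and ground-truth beat
times — so detection, labeling and classification can all be scored against
truth with no data download.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ecg_io import (
    APNEA,
    NORMAL,
    ApneaEvent,
    EcgRecording,
    MinuteLabels,
    assign_recording_class,
    events_to_minute_labels,
)

__all__ = ["SimConfig", "SimRecording", "simulate_recording", "simulate_cohort"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings.

    ``apnea_cycle_period_s`` (default 45 s, ~0.022 Hz) places the apnea
    heart-rate oscillation in the VLF band of the HRV spectrum, which is
    where cyclic apnea-related variation appears in overnight recordings.
    """

    fs: float = 100.0
    duration_min: int = 60
    base_hr: float = 70.0
    hr_jitter_sd: float = 1.0
    apnea_minute_fraction: float = 0.3
    apnea_cycle_period_s: float = 45.0
    apnea_hr_swing: float = 10.0
    apnea_ampl_swing: float = 0.3
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration_min <= 0 or self.base_hr <= 0:
            raise ValueError("fs, duration_min and base_hr must be positive")
        if not 0 <= self.apnea_minute_fraction <= 1:
            raise ValueError("apnea_minute_fraction must be in [0, 1]")
        if self.apnea_cycle_period_s <= 0:
            raise ValueError("apnea_cycle_period_s must be positive")
        if min(self.hr_jitter_sd, self.apnea_hr_swing, self.apnea_ampl_swing, self.noise_sd) < 0:
            raise ValueError("noise and modulation magnitudes must be >= 0")


@dataclass
class SimRecording:
    """A simulated recording bundled with every flavour of ground truth."""

    recording: EcgRecording
    labels: MinuteLabels
    events: list[ApneaEvent]
    beat_times_s: np.ndarray
    beat_amplitudes: np.ndarray

    @property
    def record_id(self) -> str:
        return self.recording.record_id


def _apnea_minute_mask(n_minutes: int, n_apnea: int, rng: np.random.Generator) -> np.ndarray:
    """Place exactly ``n_apnea`` apnea minutes, preferring multi-minute bouts."""
    mask = np.zeros(n_minutes, dtype=bool)
    remaining = n_apnea
    for _ in range(20 * n_minutes):
        if remaining == 0:
            break
        run = min(int(rng.integers(2, 7)), remaining)
        start = int(rng.integers(0, n_minutes))
        if start + run <= n_minutes and not mask[start : start + run].any():
            mask[start : start + run] = True
            remaining -= run
    if remaining:  # fragmented tail: fill single free minutes deterministically
        free = np.flatnonzero(~mask)
        pick = rng.permutation(free)[:remaining]
        mask[pick] = True
    return mask


def _qrs_template(fs: float) -> np.ndarray:
    """A narrow biphasic pulse: dominant R lobe with a small trailing dip."""
    tt = np.arange(-int(0.06 * fs), int(0.1 * fs) + 1) / fs
    return np.exp(-0.5 * (tt / 0.012) ** 2) - 0.3 * np.exp(-0.5 * ((tt - 0.05) / 0.025) ** 2)


def simulate_recording(cfg: SimConfig, record_id: str = "sim") -> SimRecording:
    """Generate one recording; deterministic for a fixed config (incl. seed)."""
    if cfg.duration_min < 5:
        raise ValueError("recordings must span at least 5 minutes for windowing")
    rng = np.random.default_rng(cfg.seed)
    n_minutes = cfg.duration_min
    duration_s = 60.0 * n_minutes
    n_apnea = int(round(cfg.apnea_minute_fraction * n_minutes))
    apnea_mask = _apnea_minute_mask(n_minutes, n_apnea, rng)

    # Beat train: integrate the instantaneous heart rate. Beat times snap to
    # the sample grid so ground truth aligns with what a detector can report.
    omega = 2 * np.pi / cfg.apnea_cycle_period_s
    beat_times: list[float] = []
    beat_amps: list[float] = []
    t = 0.3  # leave the first samples clear of the template's left tail
    while t < duration_s - 0.3:
        minute = min(int(t // 60), n_minutes - 1)
        hr = cfg.base_hr
        if cfg.hr_jitter_sd > 0:
            hr += rng.normal(0.0, cfg.hr_jitter_sd)
        amp = 1.0
        if apnea_mask[minute]:
            hr += cfg.apnea_hr_swing * np.sin(omega * t)
            amp += cfg.apnea_ampl_swing * np.sin(omega * t)
        hr = float(np.clip(hr, 30.0, 200.0))
        snapped = round(t * cfg.fs) / cfg.fs
        beat_times.append(snapped)
        beat_amps.append(amp)
        t += 60.0 / hr

    n_samples = int(round(duration_s * cfg.fs))
    if cfg.noise_sd > 0:
        x = rng.normal(0.0, cfg.noise_sd, n_samples)
    else:
        x = np.zeros(n_samples)
    tpl = _qrs_template(cfg.fs)
    center = int(0.06 * cfg.fs)
    for bt, amp in zip(beat_times, beat_amps):
        i0 = int(round(bt * cfg.fs)) - center
        lo, hi = max(i0, 0), min(i0 + tpl.size, n_samples)
        x[lo:hi] += amp * tpl[lo - i0 : hi - i0]

    events = [
        ApneaEvent(onset_s=60.0 * start, duration_s=60.0 * length)
        for start, length in _runs(apnea_mask)
    ]
    labels = MinuteLabels(
        record_id=record_id,
        labels=tuple(APNEA if f else NORMAL for f in apnea_mask),
    )
    derived = events_to_minute_labels(events, duration_s, record_id=record_id)
    assert derived.labels == labels.labels, "event/label bookkeeping out of sync"
    return SimRecording(
        recording=EcgRecording(record_id=record_id, samples=x, fs=cfg.fs),
        labels=labels,
        events=events,
        beat_times_s=np.asarray(beat_times),
        beat_amplitudes=np.asarray(beat_amps),
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, length) pairs."""
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(mask) - start))
    return runs


def _apnea_minute_range(cls: str, t_minutes: int) -> tuple[int, int]:
    """Feasible apnea-minute counts that realise severity class ``cls``."""
    if cls == "A":
        lo = max(100, int(np.ceil(t_minutes / 6)))
        if lo > t_minutes:
            raise ValueError(
                f"class A infeasible: needs >= {lo} apnea minutes but the "
                f"recording has only {t_minutes}"
            )
        return lo, t_minutes
    if cls == "B":
        lo = max(int(np.ceil(t_minutes / 12)), 5)
        # n <= 99 already rules class A out, whatever the AHI
        hi = min(99, t_minutes - 1)
        if hi < lo:
            raise ValueError(f"class B infeasible for a {t_minutes}-minute recording")
        return lo, hi
    if cls == "C":
        hi = int(np.ceil(t_minutes / 12)) - 1
        return 0, max(hi, 0)
    raise ValueError(f"unknown class {cls!r}")


def simulate_cohort(
    n_records: int,
    class_mix: tuple[float, float, float] = (0.0, 0.5, 0.5),
    template: SimConfig | None = None,
    seed: int = 0,
) -> list[SimRecording]:
    """Generate a cohort whose recordings realise a requested A/B/C mix.

    ``class_mix`` gives the target proportions of severity classes (A, B, C);
    counts are apportioned by largest remainder. Each recording's apnea-minute
    count is drawn from the feasible range for its class and verified post hoc
    with :func:`apneascan.ecg_io.assign_recording_class`. Record ``i`` is
    simulated with seed ``seed + i`` so cohorts are reproducible record by
    record.
    """
    if n_records < 1:
        raise ValueError("n_records must be >= 1")
    mix = np.asarray(class_mix, dtype=float)
    if mix.min() < 0 or not np.isclose(mix.sum(), 1.0):
        raise ValueError("class_mix must be non-negative and sum to 1")
    template = template or SimConfig()

    raw = mix * n_records
    counts = np.floor(raw).astype(int)
    for _ in range(n_records - counts.sum()):
        counts[np.argmax(raw - counts)] += 1
    classes = [c for c, k in zip("ABC", counts) for _ in range(k)]

    rng = np.random.default_rng(seed)
    records = []
    for i, cls in enumerate(classes):
        lo, hi = _apnea_minute_range(cls, template.duration_min)
        n_apnea = int(rng.integers(lo, hi + 1))
        cfg = replace(
            template,
            apnea_minute_fraction=n_apnea / template.duration_min,
            seed=seed + i,
        )
        rec = simulate_recording(cfg, record_id=f"sim{i:03d}")
        got = assign_recording_class(rec.labels)
        if got != cls:
            raise RuntimeError(f"record {rec.record_id}: requested class {cls}, got {got}")
        records.append(rec)
    return records
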
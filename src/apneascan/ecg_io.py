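"""Recording and annotation I/O for per-minute sleep-apnea analysis.

Recordings are single-lead ECG sample trains with a sampling rate (100 Hz by
default, matching ambulatory apnea screening hardware). Annotations come in
two dialects common in public sleep corpora:

* per-minute labels — one ``A`` (apnea) / ``N`` (normal) character per
  elapsed minute of the recording;
* event intervals — one ``onset_s duration_s`` pair per apnea/hypopnea
  event, converted to per-minute labels with the 5-second overlap rule.

Files are plain text so test fixtures need no binary payloads:

* recording: a one-line header ``# ecg id=<record_id> fs=<hz>`` followed by
  one sample value per line;
* labels: a single line of ``A``/``N`` characters;
* events: two whitespace-separated columns, ``onset_s duration_s``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

APNEA = "A"
NORMAL = "N"

__all__ = [
    "APNEA",
    "NORMAL",
    "EcgRecording",
    "MinuteLabels",
    "ApneaEvent",
    "read_recording",
    "write_recording",
    "read_minute_labels",
    "write_minute_labels",
    "read_events",
    "write_events",
    "events_to_minute_labels",
    "assign_recording_class",
]


@dataclass
class EcgRecording:
    """A single-lead ECG signal with its sampling rate.

    Parameters
    ----------
    record_id:
        Identifier of the recording (used to align labels and predictions).
    samples:
        Signal values in acquisition units (typically mV).
    fs:
        Sampling rate in Hz; must be positive.
    """

    record_id: str
    samples: np.ndarray
    fs: float = 100.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D sequence")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    @property
    def n_minutes(self) -> int:
        """Whole minutes covered by the recording (trailing part truncated)."""
        return int(self.duration_s // 60)


@dataclass
class MinuteLabels:
    """Per-minute apnea/normal annotation aligned to a recording."""

    record_id: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        if len(self.labels) == 0:
            raise ValueError("labels must be non-empty")
        bad = sorted({l for l in self.labels} - {APNEA, NORMAL})
        if bad:
            raise ValueError(f"unknown label symbols {bad}; expected 'A'/'N'")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, i):
        return self.labels[i]

    @property
    def n_apnea(self) -> int:
        return sum(1 for l in self.labels if l == APNEA)


@dataclass(frozen=True)
class ApneaEvent:
    """A continuous apnea/hypopnea episode: onset and duration in seconds."""

    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError(f"event onset must be >= 0, got {self.onset_s}")
        if not self.duration_s > 0:
            raise ValueError(f"event duration must be > 0, got {self.duration_s}")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


_HEADER_PREFIX = "# ecg"


def write_recording(rec: EcgRecording, path: os.PathLike | str) -> None:
    """Write a recording in the plain-text dialect (header + one sample/line)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{_HEADER_PREFIX} id={rec.record_id} fs={rec.fs:.10g}\n")
        np.savetxt(fh, rec.samples, fmt="%.8g")


def read_recording(path: os.PathLike | str) -> EcgRecording:
    """Read a recording written by :func:`write_recording`.

    Raises
    ------
    IOError
        If the file is missing or its header cannot be parsed; the error
        message names the offending file.
    """
    path = Path(path)
    if not path.is_file():
        raise IOError(f"recording file not found: {path}")
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith(_HEADER_PREFIX):
            raise IOError(f"unreadable recording header in {path}: {header!r}")
        try:
            fields = dict(tok.split("=", 1) for tok in header[len(_HEADER_PREFIX):].split())
            record_id = fields["id"]
            fs = float(fields["fs"])
        except (ValueError, KeyError) as exc:
            raise IOError(f"unreadable recording header in {path}") from exc
        samples = np.loadtxt(fh, ndmin=1)
    if samples.size == 0:
        raise IOError(f"recording {path} contains no samples")
    return EcgRecording(record_id=record_id, samples=samples, fs=fs)


def write_minute_labels(labels: MinuteLabels, path: os.PathLike | str) -> None:
    Path(path).write_text("".join(labels.labels) + "\n")


def read_minute_labels(path: os.PathLike | str, record_id: str | None = None) -> MinuteLabels:
    path = Path(path)
    if not path.is_file():
        raise IOError(f"label file not found: {path}")
    text = path.read_text().strip()
    return MinuteLabels(record_id=record_id or path.stem, labels=tuple(text))


def write_events(events: Iterable[ApneaEvent], path: os.PathLike | str) -> None:
    with Path(path).open("w") as fh:
        for ev in events:
            fh.write(f"{ev.onset_s:.6g} {ev.duration_s:.6g}\n")


def read_events(path: os.PathLike | str) -> list[ApneaEvent]:
    path = Path(path)
    if not path.is_file():
        raise IOError(f"event file not found: {path}")
    events = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        onset, dur = line.split()
        events.append(ApneaEvent(onset_s=float(onset), duration_s=float(dur)))
    return events


def events_to_minute_labels(
    events: Sequence[ApneaEvent],
    duration_s: float,
    min_overlap_s: float = 5.0,
    record_id: str = "",
) -> MinuteLabels:
    """Convert event-interval annotations to per-minute labels.

    Minute ``m`` covers the half-open interval ``[60m, 60(m+1))``. It is
    labeled apnea iff some *single* event overlaps it for at least
    ``min_overlap_s`` seconds — an event split across a minute boundary
    contributes its within-minute portion only, so a 6-second event straddling
    a boundary as 2 s + 4 s marks neither minute.
    """
    if not duration_s > 0:
        raise ValueError("duration_s must be positive")
    n_minutes = int(duration_s // 60)
    if n_minutes == 0:
        raise ValueError("recording shorter than one minute has no labels")
    flags = np.zeros(n_minutes, dtype=bool)
    for ev in events:
        m_lo = max(int(ev.onset_s // 60), 0)
        m_hi = min(int(np.ceil(ev.end_s / 60)), n_minutes)
        for m in range(m_lo, m_hi):
            overlap = min(ev.end_s, 60.0 * (m + 1)) - max(ev.onset_s, 60.0 * m)
            if overlap >= min_overlap_s:
                flags[m] = True
    labels = tuple(APNEA if f else NORMAL for f in flags)
    return MinuteLabels(record_id=record_id, labels=labels)


def assign_recording_class(labels: MinuteLabels) -> str:
    """Assign the recording severity class A/B/C from per-minute labels.

    With ``T`` labeled minutes and ``n`` apnea minutes, AHI = 60/T * n.
    Class A: AHI >= 10 and n >= 100 (severe, long recordings); otherwise
    class B if AHI >= 5; otherwise class C (normal). The rule set covers
    every (T, n) pair exactly once.
    """
    T = len(labels)
    n = labels.n_apnea
    ahi = 60.0 / T * n
    if ahi >= 10 and n >= 100:
        return "A"
    if ahi >= 5:
        return "B"
    return "C"
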
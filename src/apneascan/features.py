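"""Hand-crafted HRV feature set for the feature-engineering baselines.

Eighteen features per five-minute window: six time-domain statistics of the
RR intervals (RMSSD, SDNN, NN50, pNN50, mean RR, mean HR) and, for each of
the RR and amplitude channels, six spectral quantities (normalized VLF/LF/HF
band powers, LF/HF, LF/(LF+HF), HF/(LF+HF)) from a Welch estimate on the
uniformly resampled series.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import RRSeries, WindowTensor

__all__ = [
    "FEATURE_NAMES",
    "HRV_BANDS",
    "TimeDomainFeatures",
    "SpectralFeatures",
    "time_domain_features",
    "spectral_features",
    "extract_feature_vector",
    "feature_table",
    "minmax_fit_transform",
]

# Standard short-term HRV bands (Hz): very-low, low and high frequency.
HRV_BANDS: dict[str, tuple[float, float]] = {
    "vlf": (0.003, 0.04),
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.4),
}

_SPECTRAL_SUFFIXES = ("vlf_norm", "lf_norm", "hf_norm", "lf_hf_ratio", "lf_frac", "hf_frac")

FEATURE_NAMES: tuple[str, ...] = (
    "rmssd",
    "sdnn",
    "nn50",
    "pnn50",
    "mean_rr",
    "mean_hr",
    *(f"rr_{s}" for s in _SPECTRAL_SUFFIXES),
    *(f"ampl_{s}" for s in _SPECTRAL_SUFFIXES),
)


class TimeDomainFeatures(NamedTuple):
    rmssd: float
    sdnn: float
    nn50: int
    pnn50: float
    mean_rr: float
    mean_hr: float


class SpectralFeatures(NamedTuple):
    vlf_norm: float
    lf_norm: float
    hf_norm: float
    lf_hf_ratio: float
    lf_frac: float
    hf_frac: float


def time_domain_features(
    rr_s: Sequence[float] | np.ndarray,
    sdnn_convention: str = "paper",
) -> TimeDomainFeatures:
    """Time-domain HRV statistics of an RR-interval sequence (seconds).

    ``rmssd`` is the root mean square of successive differences; ``nn50``
    counts successive differences strictly exceeding 50 ms and ``pnn50``
    divides it by the number of RR intervals. ``sdnn_convention`` selects
    what SDNN is the standard deviation of: ``"paper"`` takes the successive
    differences (the wording this feature set was defined with), ``"classic"``
    the RR intervals themselves.
    """
    rr = np.asarray(rr_s, dtype=float)
    if rr.size < 2:
        raise ValueError("need at least 2 RR intervals")
    d = np.diff(rr)
    rmssd = float(np.sqrt(np.mean(d**2)))
    if sdnn_convention == "paper":
        sdnn = float(np.std(d))
    elif sdnn_convention == "classic":
        sdnn = float(np.std(rr))
    else:
        raise ValueError(f"unknown sdnn_convention {sdnn_convention!r}")
    nn50 = int(np.sum(np.abs(d) > 0.050))
    mean_rr = float(np.mean(rr))
    return TimeDomainFeatures(
        rmssd=rmssd,
        sdnn=sdnn,
        nn50=nn50,
        pnn50=nn50 / rr.size,
        mean_rr=mean_rr,
        mean_hr=60.0 / mean_rr,
    )


def spectral_features(
    series: np.ndarray,
    rate_hz: float = 3.0,
    bands: dict[str, tuple[float, float]] = HRV_BANDS,
    nperseg: int = 256,
) -> SpectralFeatures:
    """Normalized band powers of a uniformly sampled channel.

    Welch's method (segment ``nperseg``, 50% overlap, mean-detrended) gives
    the PSD; VLF/LF/HF powers are integrated over their bands and each is
    normalized by the VLF+LF+HF total. A constant series has no oscillatory
    power: every output is zero and a warning is emitted.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 64:
        raise ValueError("series too short for spectral estimation (need >= 64)")
    nper = min(nperseg, x.size)
    freqs, psd = sps.welch(x, fs=rate_hz, nperseg=nper, noverlap=nper // 2, detrend="constant")
    df = freqs[1] - freqs[0]
    power = {
        name: float(np.sum(psd[(freqs >= lo) & (freqs < hi)]) * df)
        for name, (lo, hi) in bands.items()
    }
    total = power["vlf"] + power["lf"] + power["hf"]
    if total <= 0:
        warnings.warn("degenerate constant input: zero band power", stacklevel=2)
        return SpectralFeatures(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    lf, hf = power["lf"], power["hf"]
    lf_hf = lf / hf if hf > 0 else 0.0
    denom = lf + hf
    lf_frac = lf / denom if denom > 0 else 0.0
    return SpectralFeatures(
        vlf_norm=power["vlf"] / total,
        lf_norm=lf / total,
        hf_norm=hf / total,
        lf_hf_ratio=lf_hf,
        lf_frac=lf_frac,
        hf_frac=1.0 - lf_frac if denom > 0 else 0.0,
    )


def extract_feature_vector(
    window: WindowTensor,
    rr_raw: RRSeries,
    sdnn_convention: str = "paper",
) -> np.ndarray:
    """The 18-feature vector for one window, in :data:`FEATURE_NAMES` order.

    Time-domain statistics use the (outlier-filtered) RR intervals that fall
    inside the window span; spectral features use the two interpolated
    channels of the window tensor.
    """
    t0, t1 = window.grid[0], window.grid[-1]
    sel = (rr_raw.times_s >= t0) & (rr_raw.times_s <= t1)
    td = time_domain_features(rr_raw.rr_s[sel], sdnn_convention=sdnn_convention)
    rr_sp = spectral_features(window.rr)
    ampl_sp = spectral_features(window.ampl)
    return np.array([*td, *rr_sp, *ampl_sp], dtype=float)


def feature_table(
    windows: Sequence[WindowTensor],
    rr_raw: RRSeries,
    sdnn_convention: str = "paper",
) -> pd.DataFrame:
    """Feature matrix for a recording's windows, with identifying columns."""
    rows = []
    for w in windows:
        vec = extract_feature_vector(w, rr_raw, sdnn_convention=sdnn_convention)
        rows.append(
            {"record_id": w.record_id, "minute_index": w.minute_index, "label": w.label}
            | dict(zip(FEATURE_NAMES, vec))
        )
    return pd.DataFrame(rows, columns=["record_id", "minute_index", "label", *FEATURE_NAMES])


def minmax_fit_transform(
    train: np.ndarray,
    test: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None, tuple[np.ndarray, np.ndarray]]:
    """Min-max scale features, fitting the column ranges on the training set.

    ``x* = (x - x_min) / (x_max - x_min)`` with the extrema taken over the
    training rows only; a zero-range column maps to 0 everywhere, and test
    values outside the training range are allowed outside [0, 1] (no clipping).
    Returns the scaled train matrix, scaled test matrix (or None) and the
    fitted ``(x_min, x_max)`` pair.
    """
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("training matrix must be non-empty")
    x_min = train.min(axis=0)
    x_max = train.max(axis=0)
    rng = x_max - x_min
    safe = np.where(rng > 0, rng, 1.0)
    scale = lambda x: np.where(rng > 0, (x - x_min) / safe, 0.0)
    test_out = scale(np.asarray(test, dtype=float)) if test is not None else None
    return scale(train), test_out, (x_min, x_max)
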
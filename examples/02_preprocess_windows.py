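"""From raw ECG to the 900x2 window tensors the classifier consumes.

Hamilton-style R-peak detection -> RR/amplitude series -> median outlier
filter -> cubic-spline resampling at 3 Hz -> five-minute context windows.
"""

import numpy as np

from apneascan.preprocess import (
    build_dataset,
    compute_rr_and_amplitude,
    detect_r_peaks,
    median_filter_rr,
)
from apneascan.simulate import SimConfig, simulate_recording

sim = simulate_recording(SimConfig(duration_min=10, seed=3), record_id="demo")
rec = sim.recording

peaks = detect_r_peaks(rec)
print(f"recording: {rec.duration_s:.0f} s at {rec.fs:.0f} Hz")
print(f"true beats: {len(sim.beat_times_s)}, detected R-peaks: {len(peaks)}")

rr = compute_rr_and_amplitude(peaks)
filtered = median_filter_rr(rr)
n_fixed = int(np.sum(filtered.rr_s != rr.rr_s))
print(f"RR intervals: {len(rr)} (median filter corrected {n_fixed} outliers)")
print(f"mean RR {filtered.rr_s.mean():.3f} s -> mean HR {60 / filtered.rr_s.mean():.1f} bpm")

windows = build_dataset(rec, sim.labels)
w = windows[5]
print(f"\nwindows: {len(windows)} (one per labeled minute)")
print(
    f"window for minute {w.minute_index}: span [{w.grid[0]:.0f}, {w.grid[-1] + 1/3:.0f}) s, "
    f"channels {w.channels.shape}, label {w.label}"
)
print("Each channel holds 900 uniformly spaced samples of the RR-interval")
print("and R-amplitude series over the minute and its +/-2-minute context.")
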
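"""The 18 hand-crafted HRV features and what separates apnea minutes.

Twelve features come from the RR intervals (time-domain statistics plus
normalized VLF/LF/HF band powers) and six from the R-amplitude series.
"""

import numpy as np

from apneascan.ecg_io import APNEA
from apneascan.features import FEATURE_NAMES, feature_table
from apneascan.preprocess import (
    build_dataset,
    compute_rr_and_amplitude,
    detect_r_peaks,
    median_filter_rr,
)
from apneascan.simulate import SimConfig, simulate_recording

sim = simulate_recording(
    SimConfig(duration_min=20, apnea_minute_fraction=0.5, seed=9), record_id="demo"
)
rr = median_filter_rr(compute_rr_and_amplitude(detect_r_peaks(sim.recording)))
windows = build_dataset(sim.recording, sim.labels)
table = feature_table(windows, rr)

print(f"feature table: {table.shape[0]} minutes x {len(FEATURE_NAMES)} features")
apnea = table[table.label == APNEA]
normal = table[table.label != APNEA]
print(f"\n{'feature':14s} {'apnea mean':>11s} {'normal mean':>12s}")
for name in ("rmssd", "sdnn", "mean_hr", "rr_vlf_norm", "rr_lf_norm", "ampl_vlf_norm"):
    print(f"{name:14s} {apnea[name].mean():11.4f} {normal[name].mean():12.4f}")
print()
print("Apnea minutes show more RR variability and a larger share of very-low-")
print("frequency power: the cyclic apneic heart-rate swing (period ~45 s,")
print("~0.022 Hz) falls squarely in the VLF band.")
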
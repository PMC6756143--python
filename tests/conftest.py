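import numpy as np
import pytest

from apneascan import simulate
from apneascan.ecg_io import APNEA, NORMAL
from apneascan.preprocess import WindowTensor, uniform_grid


@pytest.fixture(scope="session")
def clean_60bpm_recording():
    """Noise-free 60 bpm, 10 min, no apnea: every true RR is exactly 1 s."""
    cfg = simulate.SimConfig(
        duration_min=10, base_hr=60, hr_jitter_sd=0.0, noise_sd=0.0,
        apnea_minute_fraction=0.0, seed=11,
    )
    return simulate.simulate_recording(cfg, record_id="clean60")


@pytest.fixture(scope="session")
def small_cohort():
    """Six 12-minute recordings, half apneic (class B) and half normal."""
    return simulate.simulate_cohort(
        6, (0.0, 0.5, 0.5), simulate.SimConfig(duration_min=12), seed=5
    )


def make_synthetic_windows(n_per_class=100, n_points=900, seed=0):
    """Directly constructed, separable-by-design window tensors.

    Apnea windows carry a slow oscillation on both channels; normal windows
    are flat plus small noise. No preprocessing involved — these exercise the
    classifier contract alone.
    """
    rng = np.random.default_rng(seed)
    grid = uniform_grid(0.0, n_points / 3.0, 3.0)
    windows = []
    for i in range(2 * n_per_class):
        apnea = i % 2 == 0
        noise = rng.normal(0, 0.02, (2, n_points))
        if apnea:
            osc = 0.15 * np.sin(2 * np.pi * grid / 45.0 + rng.uniform(0, 2 * np.pi))
            rr = 0.85 + osc + noise[0]
            ampl = 1.0 + 2 * osc + noise[1]
        else:
            rr = 0.85 + noise[0]
            ampl = 1.0 + noise[1]
        windows.append(
            WindowTensor(
                record_id=f"syn{i:03d}", minute_index=i, grid=grid,
                rr=rr, ampl=ampl, label=APNEA if apnea else NORMAL,
            )
        )
    return windows


@pytest.fixture(scope="session")
def separable_windows():
    return make_synthetic_windows()
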
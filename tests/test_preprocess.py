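import numpy as np
import pytest

from apneascan import simulate
from apneascan.ecg_io import APNEA, EcgRecording, MinuteLabels, NORMAL
from apneascan.preprocess import (
    RPeakSeries,
    RRSeries,
    assemble_window,
    build_dataset,
    compute_rr_and_amplitude,
    detect_r_peaks,
    interpolate_uniform,
    median_filter_rr,
    uniform_grid,
)


def _clean_recording(bpm, minutes, seed=0):
    cfg = simulate.SimConfig(
        duration_min=minutes, base_hr=bpm, hr_jitter_sd=0.0, noise_sd=0.0,
        apnea_minute_fraction=0.0, seed=seed,
    )
    return simulate.simulate_recording(cfg, record_id=f"clean{bpm}")


class TestDetectRPeaks:
    def test_sixty_bpm_count_and_spacing(self):
        sim = _clean_recording(60, 5)
        peaks = detect_r_peaks(sim.recording)
        n_true = len(sim.beat_times_s)
        assert abs(len(peaks) - n_true) <= 1
        rr = np.diff(peaks.peak_times_s)
        assert np.all(np.abs(rr - 1.0) < 0.05)

    def test_75_bpm_five_minutes(self):
        sim = _clean_recording(75, 5)
        peaks = detect_r_peaks(sim.recording)
        assert abs(len(peaks) - len(sim.beat_times_s)) <= 2

    def test_all_zero_signal_gives_empty_series(self):
        rec = EcgRecording("flat", np.zeros(6000), fs=100)
        peaks = detect_r_peaks(rec)
        assert len(peaks) == 0

    def test_too_short_signal_rejected(self):
        rec = EcgRecording("short", np.random.default_rng(0).normal(size=150), fs=100)
        with pytest.raises(ValueError):
            detect_r_peaks(rec)

    def test_low_sampling_rate_rejected(self):
        rec = EcgRecording("slow", np.zeros(200), fs=40)
        with pytest.raises(ValueError):
            detect_r_peaks(rec)


class TestRRSeries:
    def test_definition(self):
        peaks = RPeakSeries(np.array([1.0, 2.0, 3.1]), np.array([0.9, 1.0, 1.1]))
        rr = compute_rr_and_amplitude(peaks)
        np.testing.assert_allclose(rr.rr_s, [1.0, 1.1])
        np.testing.assert_allclose(rr.times_s, [2.0, 3.1])
        np.testing.assert_allclose(rr.ampl, [1.0, 1.1])

    def test_two_peaks_minimal(self):
        rr = compute_rr_and_amplitude(RPeakSeries(np.array([0.5, 1.4]), np.array([1.0, 1.2])))
        assert len(rr) == 1

    def test_single_peak_rejected(self):
        with pytest.raises(ValueError):
            compute_rr_and_amplitude(RPeakSeries(np.array([1.0]), np.array([1.0])))

    def test_simulator_rr_near_one_second(self, clean_60bpm_recording):
        peaks = detect_r_peaks(clean_60bpm_recording.recording)
        rr = compute_rr_and_amplitude(peaks)
        assert np.all((rr.rr_s >= 0.9) & (rr.rr_s <= 1.1))


def _rr_series(values, t0=1.0):
    times = t0 + np.cumsum(values)
    return RRSeries(times_s=times, rr_s=np.asarray(values, float), ampl=np.ones(len(values)))


class TestMedianFilter:
    def test_replaces_outlier(self):
        rr = _rr_series([0.8, 0.8, 3.0, 0.8, 0.8])
        out = median_filter_rr(rr)
        np.testing.assert_allclose(out.rr_s, 0.8)

    def test_constant_unchanged(self):
        rr = _rr_series([0.9] * 7)
        np.testing.assert_array_equal(median_filter_rr(rr).rr_s, rr.rr_s)

    def test_within_tolerance_unchanged(self):
        rr = _rr_series([0.8, 0.82, 0.81, 0.79, 0.8])
        np.testing.assert_array_equal(median_filter_rr(rr).rr_s, rr.rr_s)

    def test_amplitudes_and_length_preserved(self):
        rng = np.random.default_rng(3)
        vals = 0.8 + rng.normal(0, 0.02, 50)
        vals[[10, 30]] = 2.5  # ectopic-like spikes
        rr = _rr_series(vals)
        out = median_filter_rr(rr)
        assert len(out) == len(rr)
        np.testing.assert_array_equal(out.ampl, rr.ampl)
        assert np.all(out.rr_s < 2.0)

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(4)
        vals = 0.85 + rng.normal(0, 0.03, 120)
        vals[rng.integers(0, 120, 6)] = 3.0
        once = median_filter_rr(_rr_series(vals))
        twice = median_filter_rr(once)
        np.testing.assert_array_equal(once.rr_s, twice.rr_s)

    def test_short_series_pass_through(self):
        rr = _rr_series([0.8, 3.0, 0.8])
        np.testing.assert_array_equal(median_filter_rr(rr, window=5).rr_s, rr.rr_s)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_filter_rr(_rr_series([0.8] * 10), window=4)


class TestInterpolateUniform:
    def test_five_minute_span_gives_900_points(self):
        rng = np.random.default_rng(0)
        vals = 0.9 + rng.normal(0, 0.02, 320)
        rr = _rr_series(vals, t0=1.0)
        rr_u, ampl_u = interpolate_uniform(rr, 0.0, 300.0, rate_hz=3.0)
        assert rr_u.shape == ampl_u.shape == (900,)

    def test_output_length_scales_with_span(self):
        vals = [1.0] * 200
        rr = _rr_series(vals)
        for span in (30.0, 60.0, 120.0):
            rr_u, _ = interpolate_uniform(rr, 0.0, span, rate_hz=3.0)
            assert len(rr_u) == int(3 * span)

    def test_constant_support_reproduced(self):
        rr = _rr_series([0.75] * 100)
        rr_u, _ = interpolate_uniform(rr, 0.0, 60.0)
        np.testing.assert_allclose(rr_u, 0.75, atol=1e-12)

    def test_linear_ramp_reproduced(self):
        times = np.linspace(0.5, 69.5, 80)
        slope, icpt = 0.002, 0.8
        rr = RRSeries(times_s=times, rr_s=icpt + slope * times, ampl=np.ones(80))
        rr_u, _ = interpolate_uniform(rr, 10.0, 60.0)
        grid = uniform_grid(10.0, 60.0)
        np.testing.assert_allclose(rr_u, icpt + slope * grid, atol=1e-9)

    def test_too_few_support_points_rejected(self):
        rr = _rr_series([1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="support"):
            interpolate_uniform(rr, 0.0, 10.0)


@pytest.fixture(scope="module")
def rr_and_labels():
    rng = np.random.default_rng(1)
    vals = 0.85 + rng.normal(0, 0.02, 800)
    rr = _rr_series(vals, t0=0.5)
    n_min = int(rr.times_s[-1] // 60)
    labels = MinuteLabels("w", tuple(APNEA if m % 3 == 0 else NORMAL for m in range(n_min)))
    return rr, labels, n_min


class TestAssembleWindow:

    def test_interior_window_span(self, rr_and_labels):
        rr, labels, n_min = rr_and_labels
        w = assemble_window(rr, 5, n_min, labels)
        assert w.grid[0] == 180.0
        assert len(w.rr) == len(w.ampl) == 900
        assert w.channels.shape == (900, 2)

    def test_edge_window_still_900_points(self, rr_and_labels):
        rr, labels, n_min = rr_and_labels
        for m in (0, 1, n_min - 2, n_min - 1):
            w = assemble_window(rr, m, n_min, labels)
            assert len(w.rr) == 900
            assert np.all(np.isfinite(w.rr))

    def test_label_pass_through(self, rr_and_labels):
        rr, labels, n_min = rr_and_labels
        for m in (0, 3, 7):
            assert assemble_window(rr, m, n_min, labels).label == labels[m]

    def test_recording_shorter_than_window_rejected(self, rr_and_labels):
        rr, labels, _ = rr_and_labels
        with pytest.raises(ValueError):
            assemble_window(rr, 0, 4, labels)

    def test_minute_out_of_range_rejected(self, rr_and_labels):
        rr, labels, n_min = rr_and_labels
        with pytest.raises(ValueError):
            assemble_window(rr, n_min, n_min, labels)


class TestBuildDataset:
    def test_one_tensor_per_minute_with_labels(self, clean_60bpm_recording):
        sim = clean_60bpm_recording
        windows = build_dataset(sim.recording, sim.labels)
        assert len(windows) == 10
        assert all(len(w.rr) == 900 for w in windows)
        assert tuple(w.label for w in windows) == sim.labels.labels

    def test_pipeline_deterministic(self, clean_60bpm_recording):
        sim = clean_60bpm_recording
        a = build_dataset(sim.recording, sim.labels)
        b = build_dataset(sim.recording, sim.labels)
        for wa, wb in zip(a, b):
            np.testing.assert_array_equal(wa.rr, wb.rr)
            np.testing.assert_array_equal(wa.ampl, wb.ampl)


class TestPeakRecoveryAcrossRates:
    @pytest.mark.parametrize("bpm", [40, 80, 120])
    def test_noise_free_recovery_within_one_beat(self, bpm):
        sim = _clean_recording(bpm, 5, seed=bpm)
        peaks = detect_r_peaks(sim.recording)
        true = sim.beat_times_s
        assert abs(len(peaks) - len(true)) <= 1
        dt = np.abs(peaks.peak_times_s[:, None] - true[None, :]).min(axis=0)
        assert (dt <= 0.03).mean() >= 0.99
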
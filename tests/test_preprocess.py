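"""Resampling, zero-phase high-pass, median scaling, gap validation."""
import numpy as np
import pytest

from scgbeat.datatypes import ScgRecording
from scgbeat.preprocess import (
    PreprocessParams,
    highpass,
    median_scale,
    resample,
    validate_gaps,
)


def _rec(channel: np.ndarray, fs: float) -> ScgRecording:
    return ScgRecording(np.tile(channel, (3, 1)), fs=fs)


class TestResample:
    def test_sinusoid_upsampled_matches_analytic(self):
        fs0, f = 50.0, 1.0
        t0 = np.arange(500) / fs0
        rec = _rec(np.sin(2 * np.pi * f * t0), fs0)
        out = resample(rec, 200.0)
        t1 = np.arange(out.n_samples) / 200.0
        inside = t1 <= t0[-1]  # np.interp clamps beyond the last input sample
        err = np.max(np.abs(out.data[0, inside] - np.sin(2 * np.pi * f * t1[inside])))
        assert err < 0.01

    def test_identity_when_rate_unchanged(self, clean_recording):
        rec, _ = clean_recording
        out = resample(rec, rec.fs)
        assert np.array_equal(out.data, rec.data)

    def test_length_scales_with_rate(self):
        rec = _rec(np.random.default_rng(0).standard_normal(500), 50.0)
        out = resample(rec, 200.0)
        assert abs(out.n_samples - 4 * 500) <= 1

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            resample(ScgRecording(np.zeros((3, 1)), fs=50.0), 200.0)

    def test_double_resample_equals_single(self):
        rng = np.random.default_rng(1)
        rec = _rec(rng.standard_normal(400), 100.0)
        once = resample(rec, 200.0)
        twice = resample(resample(rec, 200.0), 200.0)
        assert np.allclose(once.data, twice.data, atol=1e-12)


class TestHighpass:
    def test_dc_offset_removed(self):
        rec = _rec(np.full(2000, 7.5), 200.0)
        out = highpass(rec)
        interior = out.data[:, 200:-200]
        assert np.max(np.abs(interior)) < 1e-6 * 7.5

    def test_respiration_tone_strongly_attenuated(self):
        fs = 200.0
        t = np.arange(int(30 * fs)) / fs
        rec = _rec(np.sin(2 * np.pi * 0.3 * t), fs)
        out = highpass(rec)
        assert np.sqrt(np.mean(out.data**2)) < 0.01 * np.sqrt(
            np.mean(rec.data**2)
        )

    def test_beat_band_tone_passes(self):
        fs = 200.0
        t = np.arange(int(30 * fs)) / fs
        rec = _rec(np.sin(2 * np.pi * 15.0 * t), fs)
        out = highpass(rec)
        # <= 1 dB attenuation
        ratio = np.sqrt(np.mean(out.data**2) / np.mean(rec.data**2))
        assert ratio > 10 ** (-1 / 20)

    def test_zero_phase_preserves_pulse_peak(self):
        fs = 200.0
        x = np.zeros(4000)
        c = 2000
        x[c - 50 : c + 51] = np.hanning(101)
        out = highpass(_rec(x, fs))
        assert np.argmax(out.data[0]) == c

    def test_idempotent_on_in_band_content(self):
        fs = 200.0
        t = np.arange(int(30 * fs)) / fs
        rec = _rec(np.sin(2 * np.pi * 15.0 * t), fs)
        once = highpass(rec)
        twice = highpass(once)
        core = slice(int(2 * fs), -int(2 * fs))  # edge transients excluded
        rms = np.sqrt(np.mean(once.data[:, core] ** 2))
        diff = np.sqrt(np.mean((twice.data[:, core] - once.data[:, core]) ** 2))
        assert diff < 1e-3 * rms

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            highpass(_rec(np.zeros(10), 200.0))


class TestMedianScale:
    def test_alternating_bounds_map_to_unit(self):
        seg = 64
        ch = np.tile([-2.0, 2.0], 10 * seg // 2)
        out = median_scale(_rec(ch, 200.0), PreprocessParams(scale_segment_len=seg))
        assert np.allclose(np.unique(out.data), [-1.0, 1.0])

    def test_spike_window_does_not_distort_bounds(self):
        # 9 normal windows at +-1 plus one window holding a 100x spike:
        # medians of window mins/maxs stay at +-1, spike clips at 1.5.
        seg = 100
        rng = np.random.default_rng(0)
        windows = []
        for _ in range(9):
            w = rng.uniform(-0.9, 0.9, seg)
            w[0], w[1] = -1.0, 1.0
            windows.append(w)
        spike = np.zeros(seg)
        spike[50] = 100.0
        windows.append(spike)
        ch = np.concatenate(windows)
        out = median_scale(_rec(ch, 200.0), PreprocessParams(scale_segment_len=seg))
        # hand-computed: m = median of mins = -1, M = median of maxs = 1
        assert out.data[0][950] == 1.5  # clipped spike
        assert np.allclose(out.data[0][:900], ch[:900], atol=1e-12)

    def test_flat_channel_maps_to_zero(self):
        out = median_scale(_rec(np.full(1000, 3.3), 200.0))
        assert np.all(out.data == 0.0)

    def test_scaling_is_monotone(self, rng):
        ch = rng.standard_normal(5000)
        out = median_scale(_rec(ch, 200.0), PreprocessParams(scale_segment_len=512))
        order_in = np.argsort(ch)
        scaled = out.data[0][order_in]
        # monotone non-decreasing up to clipping plateaus
        assert np.all(np.diff(scaled) >= -1e-12)


class TestValidateGaps:
    def test_uniform_timestamps_single_run(self):
        ts = np.arange(1000) / 200.0
        assert validate_gaps(ts, 0.05) == [(0, 1000)]

    def test_single_gap_splits_in_two(self):
        ts = np.concatenate([np.arange(100) / 200.0, 2.0 + np.arange(100) / 200.0])
        assert validate_gaps(ts, 0.05) == [(0, 100), (100, 200)]

    def test_all_gaps_too_large_gives_singletons(self):
        ts = np.arange(50) * 0.06
        runs = validate_gaps(ts, 0.05)
        assert runs == [(i, i + 1) for i in range(50)]

    def test_brute_force_agreement(self, rng):
        for _ in range(50):
            gaps = rng.choice([0.004, 0.005, 0.06, 0.2], size=99)
            ts = np.concatenate([[0.0], np.cumsum(gaps)])
            runs = validate_gaps(ts, 0.05)
            # brute force: pairwise scan
            member = np.zeros(100, dtype=int)
            run_id = 0
            for i in range(1, 100):
                if ts[i] - ts[i - 1] > 0.05:
                    run_id += 1
                member[i] = run_id
            expected = [
                (int(np.flatnonzero(member == r)[0]),
                 int(np.flatnonzero(member == r)[-1]) + 1)
                for r in range(run_id + 1)
            ]
            assert runs == expected

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError):
            validate_gaps(np.array([0.0, 0.1, 0.05]), 0.05)
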
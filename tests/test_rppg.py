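import numpy as np
import pytest

from vbpe import synthetic as syn
from vbpe.errors import InputError
from vbpe.landmarks import LandmarkSet, RoiPolygon, VideoClip, construct_roi
from vbpe.rppg import (
    PpgSignal,
    RgbTrace,
    bandpass,
    chrom_extract,
    mean_rgb_trace,
    uniform_trace,
)


def _roi(x0, y0, x1, y1, frame=0, site="forehead"):
    return RoiPolygon(
        site=site,
        vertices=[(x0, y0), (x1, y0), (x1, y1), (x0, y1)],
        frame_index=frame,
    )


def _dominant_hz(x, fs):
    x = np.asarray(x) - np.mean(x)
    spec = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), 1 / fs)
    return freqs[spec.argmax()]


class TestMeanRgbTrace:
    def test_uniform_frame_returns_its_value(self):
        frames = np.zeros((1, 50, 60, 3), dtype=np.uint8)
        frames[..., 0], frames[..., 1], frames[..., 2] = 120, 80, 60
        video = VideoClip(frames=frames, fps=30.0)
        trace = mean_rgb_trace(video, [_roi(5, 5, 40, 40)])
        np.testing.assert_allclose(trace.samples[0], [120.0, 80.0, 60.0])

    def test_half_and_half_averages(self):
        from vbpe.rppg import roi_mask

        frames = np.zeros((1, 20, 20, 3), dtype=np.uint8)
        roi = _roi(0, 0, 19, 19)
        rr, cc = roi_mask(roi, (20, 20))
        half = len(rr) // 2
        frames[0, rr[:half], cc[:half]] = [0, 0, 0]
        frames[0, rr[half : 2 * half], cc[half : 2 * half]] = [2, 4, 6]
        frames[0, rr[2 * half :], cc[2 * half :]] = [1, 2, 3]  # odd leftover
        video = VideoClip(frames=frames, fps=30.0)
        trace = mean_rgb_trace(video, [roi])
        np.testing.assert_allclose(trace.samples[0], [1.0, 2.0, 3.0])

    def test_single_pixel_roi_returns_that_pixel(self):
        frames = np.zeros((1, 20, 20, 3), dtype=np.uint8)
        frames[0, 7, 7] = [9, 8, 7]
        video = VideoClip(frames=frames, fps=30.0)
        roi = _roi(6.6, 6.6, 7.4, 7.4)  # encloses only pixel centre (7, 7)
        trace = mean_rgb_trace(video, [roi])
        np.testing.assert_allclose(trace.samples[0], [9.0, 8.0, 7.0])

    def test_empty_interior_errors(self):
        video = VideoClip(frames=np.zeros((1, 20, 20, 3), np.uint8), fps=30.0)
        degenerate = RoiPolygon(
            site="forehead",
            vertices=[(5.6, 5.6), (5.9, 5.6), (5.9, 5.7)],
            frame_index=0,
        )
        with pytest.raises(InputError, match="interior"):
            mean_rgb_trace(video, [degenerate])

    def test_uniform_trace_bridges_dropped_frames(self):
        samples = np.array([[0, 0, 0], [30, 30, 30]], dtype=float)
        trace = RgbTrace("face", samples, fs=30.0, frame_indices=[0, 3])
        filled = uniform_trace(trace, frame_count=4)
        np.testing.assert_allclose(filled.samples[:, 0], [0.0, 10.0, 20.0, 30.0])


class TestBandpass:
    def test_passband_tone_preserved(self):
        fs, f0 = 60.0, 1.0
        t = np.arange(int(30 * fs)) / fs
        x = PpgSignal("face", np.sin(2 * np.pi * f0 * t), fs)
        y = bandpass(x).samples
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        amp = y[mid].max()
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_drift_tone_attenuated(self):
        fs, f0 = 60.0, 0.05
        t = np.arange(int(120 * fs)) / fs
        x = PpgSignal("face", np.sin(2 * np.pi * f0 * t), fs)
        y = bandpass(x).samples
        mid = slice(len(t) // 4, 3 * len(t) // 4)
        assert np.abs(y[mid]).max() < 0.10

    def test_constant_signal_rejected_to_zero(self):
        x = PpgSignal("face", np.full(600, 3.3), 60.0)
        np.testing.assert_allclose(bandpass(x).samples, 0.0, atol=1e-9)

    def test_cutoff_at_nyquist_errors_at_high_fs(self):
        x = PpgSignal("face", np.random.default_rng(0).normal(size=600), 80.0)
        with pytest.raises(InputError, match="Nyquist"):
            bandpass(x, high=40.0)

    def test_cutoff_clipped_at_minimum_frame_rate(self):
        x = PpgSignal("face", np.random.default_rng(0).normal(size=600), 30.0)
        with pytest.warns(UserWarning, match="clipping"):
            y = bandpass(x, high=15.0)
        assert np.all(np.isfinite(y.samples))

    def test_zero_phase_keeps_peak_positions(self):
        spec = syn.SignalSpec(duration_s=30.0, beat_jitter_cv=0.0, seed=0)
        face, _, beats = syn.generate_ppg_pair(spec)
        from scipy.signal import find_peaks

        raw_peaks, _ = find_peaks(face.samples, distance=24)
        filt_peaks, _ = find_peaks(bandpass(face).samples, distance=24)
        interior = (raw_peaks > 100) & (raw_peaks < len(face.samples) - 100)
        for rp in raw_peaks[interior]:
            assert np.abs(filt_peaks - rp).min() <= 1


class TestChrom:
    def test_constant_trace_warns_and_returns_zero(self):
        trace = RgbTrace("face", np.tile([150.0, 110.0, 85.0], (600, 1)), 60.0)
        with pytest.warns(UserWarning, match="pulsatile"):
            out = chrom_extract(trace)
        np.testing.assert_allclose(out.samples, 0.0)

    def test_dominant_frequency_matches_pulse_rate(self):
        spec = syn.SignalSpec(duration_s=60.0, heart_rate_bpm=72.0,
                              beat_jitter_cv=0.0, seed=2)
        trace, _ = syn.modulated_rgb_trace(spec)
        out = chrom_extract(trace)
        assert _dominant_hz(out.samples, 60.0) == pytest.approx(1.2, abs=0.05)

    def test_common_illumination_drift_suppressed(self):
        spec = syn.SignalSpec(duration_s=60.0, heart_rate_bpm=72.0,
                              beat_jitter_cv=0.0, drift_amplitude=0.05,
                              drift_hz=0.05, seed=2)
        trace, _ = syn.modulated_rgb_trace(spec)
        out = bandpass(chrom_extract(trace))
        assert _dominant_hz(out.samples, 60.0) == pytest.approx(1.2, abs=0.05)
        spec_amp = np.abs(np.fft.rfft(out.samples - out.samples.mean()))
        freqs = np.fft.rfftfreq(len(out.samples), 1 / 60.0)
        drift_power = spec_amp[(freqs > 0.01) & (freqs < 0.15)].max()
        pulse_power = spec_amp[np.abs(freqs - 1.2) < 0.05].max()
        assert drift_power < 0.05 * pulse_power

    def test_invariant_to_common_channel_gain(self):
        spec = syn.SignalSpec(duration_s=20.0, seed=4)
        trace, _ = syn.modulated_rgb_trace(spec)
        scaled = RgbTrace(trace.site, 1.7 * trace.samples, trace.fs)
        a = chrom_extract(trace).samples
        b = chrom_extract(scaled).samples
        np.testing.assert_allclose(a, b, rtol=1e-6, atol=1e-9 * np.abs(a).max())

    def test_deterministic_bit_identical(self):
        spec = syn.SignalSpec(duration_s=20.0, noise_sd=0.05, seed=5)
        t1, _ = syn.modulated_rgb_trace(spec)
        t2, _ = syn.modulated_rgb_trace(spec)
        a = bandpass(chrom_extract(t1)).samples
        b = bandpass(chrom_extract(t2)).samples
        assert np.array_equal(a, b)


class TestOnVideo:
    def test_video_trace_tracks_generating_signal(self, skin_video):
        spec, res = skin_video
        trace = mean_rgb_trace(res.video, res.forehead_rois, site="face")
        g = trace.samples[:, 1]
        corr = np.corrcoef(g, res.face_signal)[0, 1]
        # darkening convention: trace anticorrelates with the pulse
        assert corr < -0.99

    def test_zero_modulation_clip_warns_no_pulse(self):
        spec = syn.SignalSpec(duration_s=4.0, seed=0)
        layout = syn.VideoLayout(depths=(0.0, 0.0, 0.0))
        res = syn.generate_skin_video(spec, layout=layout)
        trace = mean_rgb_trace(res.video, res.forehead_rois, site="face")
        with pytest.warns(UserWarning, match="pulsatile"):
            chrom_extract(trace)
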
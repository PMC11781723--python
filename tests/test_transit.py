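import numpy as np
import pytest

from vbpe import synthetic as syn
from vbpe.errors import InputError, SignalQualityError
from vbpe.rppg import PpgSignal, bandpass
from vbpe.transit import (
    EventPairs,
    PeakTrain,
    compute_transit_times,
    detect_events,
    mean_transit_time,
    pair_events,
)

FS = 60.0


def _sine(freq=1.0, duration=10.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return PpgSignal("face", np.sin(2 * np.pi * freq * t), fs)


def _train(times, site="face", kind="peak", fs=FS):
    return PeakTrain(site=site, kind=kind,
                     indices=np.round(np.asarray(times) * fs).astype(int), fs=fs)


class TestDetectEvents:
    def test_sine_peaks_at_quarter_period(self):
        peaks = detect_events(_sine(), "peak")
        expected = 0.25 + np.arange(10)
        assert len(peaks) == 10
        np.testing.assert_allclose(peaks.times, expected, atol=1 / FS)

    def test_valleys_equal_peaks_of_negated_signal(self):
        sig = bandpass(syn.generate_ppg_pair(syn.SignalSpec(seed=3))[0])
        neg = PpgSignal(sig.site, -sig.samples, sig.fs)
        v = detect_events(sig, "valley")
        p = detect_events(neg, "peak")
        np.testing.assert_array_equal(v.indices, p.indices)

    def test_recovers_every_generated_beat(self):
        spec = syn.SignalSpec(duration_s=60.0, heart_rate_bpm=62.0, seed=11)
        face, _, beats = syn.generate_ppg_pair(spec)
        peaks = detect_events(bandpass(face), "peak")
        # each true beat has a detected systolic peak ~0.18 T later
        offset = syn._SYS_OFFSET * spec.beat_period_s
        for b in beats:
            if b + offset > peaks.times[-1]:
                continue
            assert np.abs(peaks.times - (b + offset)).min() <= 2 / FS

    def test_too_few_events_errors(self):
        with pytest.raises(SignalQualityError, match="too short/noisy"):
            detect_events(_sine(duration=2.0), "peak")


class TestPairEvents:
    def test_constant_shift_pairs_everything(self):
        face = _train(np.arange(10) + 0.25)
        hand = _train(np.arange(10) + 0.25 + 2 / FS, site="hand")
        pairs = pair_events(face, hand)
        assert len(pairs) == 10
        gaps = pairs.pairs[:, 1] - pairs.pairs[:, 0]
        np.testing.assert_allclose(gaps, 2 / FS, atol=1e-12)

    def test_missing_beat_leaves_one_unmatched(self):
        times = np.arange(10) + 0.25
        face = _train(times)
        hand = _train(np.delete(times, 7) + 0.02, site="hand")
        pairs = pair_events(face, hand)
        assert len(pairs) == 9
        assert pairs.unmatched_face == 1 and pairs.unmatched_hand == 0

    def test_offset_beyond_max_lag_pairs_nothing(self):
        face = _train(np.arange(10) + 0.25)
        hand = _train(np.arange(10) + 0.25 + 0.45, site="hand")
        pairs = pair_events(face, hand, max_lag=0.1)
        assert len(pairs) == 0
        with pytest.raises(SignalQualityError):
            mean_transit_time(pairs)

    def test_empty_train_errors(self):
        face = _train(np.arange(10) + 0.25)
        empty = PeakTrain("hand", "peak", np.array([], dtype=int), FS)
        with pytest.raises(InputError, match="empty"):
            pair_events(face, empty)


class TestMeanTransitTime:
    def test_constant_gaps(self):
        pairs = EventPairs(
            pairs=[(t, t + 0.033) for t in range(6)], unmatched_face=0,
            unmatched_hand=0,
        )
        assert mean_transit_time(pairs) == pytest.approx(0.033)

    def test_arithmetic_mean_of_gaps(self):
        gaps = [0.02, 0.03, 0.04, 0.02, 0.03, 0.04]
        pairs = EventPairs(
            pairs=[(t, t + g) for t, g in enumerate(gaps)],
            unmatched_face=0, unmatched_hand=0,
        )
        assert mean_transit_time(pairs) == pytest.approx(np.mean(gaps))

    def test_signed_convention_keeps_direction(self):
        pairs = EventPairs(
            pairs=[(t, t - 0.03) for t in range(6)], unmatched_face=0,
            unmatched_hand=0,
        )
        assert mean_transit_time(pairs) == pytest.approx(0.03)
        assert mean_transit_time(pairs, signed=True) == pytest.approx(-0.03)


class TestComputeTransitTimes:
    @pytest.mark.parametrize("delay_samples", [1, 4, 10])
    def test_pure_delay_recovered_within_one_sample(self, delay_samples):
        spec = syn.SignalSpec(duration_s=60.0, seed=delay_samples,
                              transit_delay_s=delay_samples / FS)
        face, hand, _ = syn.generate_ppg_pair(spec)
        tt = compute_transit_times(bandpass(face), bandpass(hand))
        assert abs(tt.ptt_s - delay_samples / FS) <= 1 / FS
        assert abs(tt.ptt_d - delay_samples / FS) <= 1 / FS
        assert tt.n_pairs_s >= 5 and tt.n_pairs_d >= 5

    def test_zero_delay_flagged(self):
        spec = syn.SignalSpec(duration_s=30.0, seed=2, transit_delay_s=0.0)
        face, hand, _ = syn.generate_ppg_pair(spec)
        with pytest.warns(UserWarning, match="PTT = 0"):
            tt = compute_transit_times(bandpass(face), bandpass(hand))
        assert tt.ptt_s == 0.0 and tt.ptt_d == 0.0

    def test_separate_peak_and_valley_delays(self):
        spec = syn.SignalSpec(duration_s=120.0, seed=6, peak_delay_s=0.03,
                              valley_delay_s=0.05, transit_delay_s=0.03)
        face, hand, _ = syn.generate_ppg_pair(spec)
        tt = compute_transit_times(bandpass(face), bandpass(hand))
        assert tt.ptt_s == pytest.approx(0.03, abs=2 / FS)
        assert tt.ptt_d == pytest.approx(0.05, abs=2 / FS)
        assert tt.ptt_d > tt.ptt_s

    def test_symmetric_under_site_swap(self):
        spec = syn.SignalSpec(duration_s=60.0, seed=8, transit_delay_s=3 / FS)
        face, hand, _ = syn.generate_ppg_pair(spec)
        a = compute_transit_times(bandpass(face), bandpass(hand))
        b = compute_transit_times(bandpass(hand), bandpass(face))
        assert a.ptt_s == pytest.approx(b.ptt_s, abs=1e-12)
        assert a.ptt_d == pytest.approx(b.ptt_d, abs=1e-12)
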
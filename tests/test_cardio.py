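"""Cardio video analysis: tiles, motion signals, periodogram, classification."""

import numpy as np
import pytest

from zfscreen.cardio_analysis import (
    BRADYCARDIA_BEATS_PER_15S,
    CardioThresholds,
    FrameStack,
    SpectralPeak,
    analyze_video,
    classify_cardio,
    compute_motion_signals,
    compute_periodogram,
    compute_reference,
    detect_significant_peaks,
    quality_control,
)
from zfscreen.phantom_generator import HeartPhantomParams, make_heart_video
from zfscreen.plate_model import CardioCategory


def _stack(frames, fps=30.0):
    return FrameStack(frames=np.asarray(frames, dtype=float), fps=fps)


class TestComputeReference:
    def test_constant_stack_gives_constant_tiles(self):
        stack = _stack(np.full((64, 16, 16), 7.0))
        ref = compute_reference(stack, tile_px=8)
        assert np.allclose(ref, 7.0)

    def test_alternating_frames_average(self):
        frames = np.zeros((64, 16, 16))
        frames[1::2] = 2.0
        ref = compute_reference(_stack(frames), tile_px=8)
        assert np.allclose(ref, 1.0)

    def test_matches_bruteforce_tile_means(self):
        stack, _ = make_heart_video(HeartPhantomParams(n_frames=64, seed=7))
        tile = 8
        ref = compute_reference(stack, tile_px=tile)
        h, w = stack.shape
        expected = []
        for r0 in range(0, h, tile):
            for c0 in range(0, w, tile):
                expected.append(stack.frames[:, r0 : r0 + tile, c0 : c0 + tile].mean())
        assert np.allclose(ref, expected)

    def test_edge_remainder_tiles(self):
        frames = np.arange(64 * 10 * 13, dtype=float).reshape(64, 10, 13)
        ref = compute_reference(_stack(frames), tile_px=8)
        # 2x2 tile grid: (8 + 2 remainder rows) x (8 + 5 remainder cols)
        assert ref.shape == (4,)
        assert ref[3] == pytest.approx(frames[:, 8:, 8:].mean())


class TestMotionSignals:
    def test_constant_video_is_motionless(self):
        stack = _stack(np.full((64, 16, 16), 3.0))
        signals = compute_motion_signals(stack, compute_reference(stack))
        assert np.allclose(signals.ed, 0.0)
        assert signals.of_amplitude == 0.0

    def test_single_differing_frame_is_local(self):
        frames = np.full((128, 16, 16), 10.0)
        frames[50] = 20.0
        stack = _stack(frames)
        signals = compute_motion_signals(stack, compute_reference(stack))
        # one strongly deviating sample; the rest share a small common offset
        assert np.argmax(signals.ed) == 50
        others = np.delete(signals.ed, 50)
        assert np.ptp(others) == pytest.approx(0.0, abs=1e-9)

    def test_sinusoidal_tile_matches_closed_form(self):
        t = np.arange(128)
        frames = np.full((128, 16, 16), 50.0)
        wave = 5.0 * np.sin(2 * np.pi * 4 * t / 128)  # integer periods: zero mean
        frames[:, :8, :8] += wave[:, None, None]
        stack = _stack(frames)
        signals = compute_motion_signals(stack, compute_reference(stack))
        # deviation lives in one tile of a 2x2 tiling: ed[t] = |wave[t]|
        assert np.allclose(signals.ed, np.abs(wave), atol=1e-9)

    def test_geometry_mismatch_rejected(self):
        stack = _stack(np.zeros((64, 16, 16)))
        with pytest.raises(ValueError, match="geometry"):
            compute_motion_signals(stack, np.zeros(3))

    def test_intensity_scaling_scales_ed_linearly(self):
        stack, _ = make_heart_video(HeartPhantomParams(n_frames=128, seed=1))
        signals = compute_motion_signals(stack, compute_reference(stack))
        scaled = _stack(stack.frames * 3.0)
        scaled_signals = compute_motion_signals(scaled, compute_reference(scaled))
        assert np.allclose(scaled_signals.ed, 3.0 * signals.ed)


class TestQualityControl:
    def test_drifting_embryo_rejected(self):
        stack, truth = make_heart_video(
            HeartPhantomParams(drift_px_per_frame=0.05, noise_sd=2.0, seed=3)
        )
        signals = compute_motion_signals(stack, compute_reference(stack))
        assert truth.drifting
        assert quality_control(signals, stack.fps) is False

    def test_clean_beating_video_passes(self):
        stack, _ = make_heart_video(HeartPhantomParams(noise_sd=2.0, seed=4))
        signals = compute_motion_signals(stack, compute_reference(stack))
        assert quality_control(signals, stack.fps) is True

    def test_constant_video_passes(self):
        stack = _stack(np.full((64, 16, 16), 1.0))
        signals = compute_motion_signals(stack, compute_reference(stack))
        assert quality_control(signals, stack.fps) is True


class TestPeriodogram:
    def test_sinusoid_peak_within_one_padded_bin(self):
        t = np.arange(512) / 30.0
        x = np.sin(2 * np.pi * 2.4 * t)
        spec = compute_periodogram(x, 30.0, pad_factor=8)
        est = spec.freqs[np.argmax(spec.power)]
        assert abs(est - 2.4) <= 30.0 / (8 * 512)

    def test_zero_series_gives_zero_power(self):
        spec = compute_periodogram(np.zeros(512), 30.0)
        assert np.all(spec.power == 0)

    def test_power_zeroed_outside_band(self):
        t = np.arange(512) / 30.0
        x = np.sin(2 * np.pi * 0.2 * t) + np.sin(2 * np.pi * 2.0 * t)
        spec = compute_periodogram(x, 30.0, band_hz=(0.5, 8.0))
        assert np.all(spec.power[~spec.in_band()] == 0)

    def test_grid_spacing(self):
        spec = compute_periodogram(np.random.default_rng(0).normal(size=512), 30.0, pad_factor=4)
        assert np.diff(spec.freqs)[0] == pytest.approx(30.0 / (4 * 512))

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="band"):
            compute_periodogram(np.zeros(512), 30.0, band_hz=(9.0, 8.0))

    def test_invalid_pad_factor_rejected(self):
        with pytest.raises(ValueError, match="pad_factor"):
            compute_periodogram(np.zeros(512), 30.0, pad_factor=3)

    def test_white_noise_rarely_yields_significant_peaks(self):
        clean = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(0, 1, 512)
            spec = compute_periodogram(x, 30.0)
            peaks = detect_significant_peaks(spec)
            if not any(p.is_significant for p in peaks):
                clean += 1
        assert clean >= 95


class TestDetectSignificantPeaks:
    def test_control_phantom_has_one_significant_frequency(self):
        stack, _ = make_heart_video(
            HeartPhantomParams(f_atrial_hz=2.8, f_ventricular_hz=2.8, noise_sd=2.0, seed=5)
        )
        signals = compute_motion_signals(stack, compute_reference(stack))
        peaks = detect_significant_peaks(compute_periodogram(signals.ed, stack.fps))
        sig = [p for p in peaks if p.is_significant]
        assert len(sig) == 1
        assert sig[0].freq_hz == pytest.approx(2.8, abs=0.05)

    def test_two_one_block_phantom_has_two_significant_frequencies(self):
        stack, _ = make_heart_video(
            HeartPhantomParams(
                f_atrial_hz=2.6, f_ventricular_hz=1.3, amp_ratio=0.7, noise_sd=2.0, seed=6
            )
        )
        signals = compute_motion_signals(stack, compute_reference(stack))
        peaks = detect_significant_peaks(compute_periodogram(signals.ed, stack.fps))
        sig = [p for p in peaks if p.is_significant]
        assert len(sig) >= 2
        assert sig[0].freq_hz == pytest.approx(1.3, abs=0.05)
        assert any(abs(p.freq_hz - 2.6) < 0.05 for p in sig)

    def test_empty_spectrum_has_no_peaks(self):
        spec = compute_periodogram(np.zeros(512), 30.0)
        assert detect_significant_peaks(spec) == []


class TestClassifyCardio:
    def _peak(self, f, power=1.0, significant=True):
        return SpectralPeak(freq_hz=f, power=power, is_significant=significant)

    def test_low_motion_is_cardiac_arrest(self, thresholds):
        result = classify_cardio([], of_amplitude=0.0, thresholds=thresholds)
        assert result.category is CardioCategory.CARDIAC_ARREST
        assert result.heart_rate_hz == 0.0

    def test_rate_just_below_cutoff_is_bradycardia(self, thresholds):
        # 2.40 Hz -> 36.0 beats per 15 s, below the 36.5 cutoff
        result = classify_cardio([self._peak(2.40)], 10.0, thresholds)
        assert result.beats_per_15s == pytest.approx(36.0)
        assert result.category is CardioCategory.BRADYCARDIA

    def test_rate_above_cutoff_is_no_effect(self, thresholds):
        result = classify_cardio([self._peak(2.60)], 10.0, thresholds)
        assert result.beats_per_15s == pytest.approx(39.0)
        assert result.category is CardioCategory.NO_EFFECT

    def test_cutoff_is_strict_less_than(self, thresholds):
        at_cutoff = classify_cardio(
            [self._peak(BRADYCARDIA_BEATS_PER_15S / 15.0)], 10.0, thresholds
        )
        assert at_cutoff.category is CardioCategory.NO_EFFECT

    def test_two_rhythms_are_arrhythmia(self, thresholds):
        peaks = [self._peak(1.3), self._peak(2.6, power=0.8)]
        result = classify_cardio(peaks, 10.0, thresholds)
        assert result.category is CardioCategory.ARRHYTHMIA_21
        assert result.heart_rate_hz == pytest.approx(1.3)

    def test_motion_without_rhythm_is_no_call(self, thresholds):
        result = classify_cardio([], of_amplitude=10.0, thresholds=thresholds)
        assert result.category is CardioCategory.NO_CALL


class TestEndToEnd:
    def test_noiseless_control_reports_39_beats(self, thresholds):
        stack, truth = make_heart_video(
            HeartPhantomParams(f_atrial_hz=2.6, f_ventricular_hz=2.6, noise_sd=0.0)
        )
        result = analyze_video(stack, thresholds)
        assert result.category is truth.category is CardioCategory.NO_EFFECT
        assert result.beats_per_15s == pytest.approx(39.0, abs=15 * 30 / 4096)

    def test_constant_video_is_cardiac_arrest(self, thresholds):
        stack = _stack(np.full((512, 64, 64), 40.0))
        result = analyze_video(stack, thresholds)
        assert result.category is CardioCategory.CARDIAC_ARREST

    def test_circular_time_shift_preserves_call(self, thresholds):
        stack, _ = make_heart_video(
            HeartPhantomParams(f_atrial_hz=2.2, f_ventricular_hz=2.2, noise_sd=2.0, seed=8)
        )
        base = analyze_video(stack, thresholds)
        shifted = FrameStack(frames=np.roll(stack.frames, 97, axis=0), fps=stack.fps)
        rolled = analyze_video(shifted, thresholds)
        assert rolled.category is base.category
        # the Hann window breaks exact shift invariance; the estimate must
        # stay within one padded-DFT bin
        assert abs(rolled.heart_rate_hz - base.heart_rate_hz) <= 30.0 / 4096

    def test_intensity_scaling_preserves_category(self, thresholds):
        stack, _ = make_heart_video(
            HeartPhantomParams(f_atrial_hz=3.0, f_ventricular_hz=3.0, noise_sd=2.0, seed=9)
        )
        base = analyze_video(stack, thresholds)
        scaled = FrameStack(frames=stack.frames * 2.5, fps=stack.fps)
        result = analyze_video(scaled, thresholds)
        assert result.category is base.category
        assert result.heart_rate_hz == pytest.approx(base.heart_rate_hz, abs=1e-9)


class TestFrameStackInvariants:
    def test_too_few_frames_rejected(self):
        with pytest.raises(ValueError, match="64"):
            FrameStack(frames=np.zeros((10, 8, 8)))

    def test_nonpositive_fps_rejected(self):
        with pytest.raises(ValueError, match="fps"):
            FrameStack(frames=np.zeros((64, 8, 8)), fps=0.0)
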
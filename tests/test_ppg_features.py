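"""Beat detection, pulse-width geometry, variability series and spectra."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ppghemo import (
    BeatDetectionError,
    PPGRecording,
    build_variability_series,
    compute_pulse_width,
    detect_beats,
    estimate_psd,
    extract_ppg_features,
    spectral_features,
)
from ppghemo.ppg_features import VariabilitySpectrum
from ppghemo.synthetic import SynthPPGConfig, generate_ppg


class TestComputePulseWidth:
    FS = 500.0

    def test_triangular_half_height_chord(self):
        # symmetric triangle of base B: chord at half height spans B/2
        fs, base_s, interval = self.FS, 0.4, 1.0
        t = np.arange(0, interval, 1 / fs)
        w = np.clip(1 - np.abs(t - 0.5) / (base_s / 2), 0, None)
        width = compute_pulse_width(w, fs, interval)
        assert width == pytest.approx((base_s / 2) / interval, abs=1.5 / fs)

    def test_rectangular_width_is_duration(self):
        fs, dur, interval = self.FS, 0.25, 1.0
        t = np.arange(0, interval, 1 / fs)
        w = (np.abs(t - 0.5) <= dur / 2).astype(float)
        assert compute_pulse_width(w, fs, interval) == pytest.approx(
            dur / interval, abs=1.5 / fs
        )

    def test_gaussian_fwhm_closed_form(self):
        fs, sigma, interval = self.FS, 0.08, 1.0
        t = np.arange(0, interval, 1 / fs)
        w = np.exp(-0.5 * ((t - 0.5) / sigma) ** 2)
        expected = 2 * math.sqrt(2 * math.log(2)) * sigma / interval
        assert compute_pulse_width(w, fs, interval) == pytest.approx(
            expected, abs=0.5 / fs
        )

    def test_flat_window_rejected(self):
        with pytest.raises(ValueError):
            compute_pulse_width(np.ones(100), self.FS, 1.0)

    def test_window_not_crossing_half_rejected(self):
        # monotone ramp: no descent below half on the right of the peak
        with pytest.raises(ValueError, match="half amplitude"):
            compute_pulse_width(np.linspace(0, 1, 100), self.FS, 1.0)

    @given(
        gain=st.floats(0.1, 50.0),
        offset=st.floats(-100.0, 100.0),
    )
    def test_affine_invariance(self, gain, offset):
        fs = 250.0
        t = np.arange(0, 1.0, 1 / fs)
        w = np.exp(-0.5 * ((t - 0.5) / 0.1) ** 2)
        base = compute_pulse_width(w, fs, 1.0)
        scaled = compute_pulse_width(gain * w + offset, fs, 1.0)
        assert scaled == pytest.approx(base, rel=1e-9)


class TestDetectBeats:
    def test_clean_60bpm_count(self, clean_recording):
        beats = detect_beats(clean_recording)
        assert 59 <= len(beats) <= 61

    def test_equal_amplitudes_without_modulation(self, clean_recording):
        beats = detect_beats(clean_recording)
        assert np.ptp(beats.amplitude) < 1e-6 * beats.amplitude.mean()

    def test_constant_signal_is_empty_result_error(self):
        rec = PPGRecording(np.ones(200 * 30), fs=200.0)
        with pytest.raises(BeatDetectionError):
            detect_beats(rec)

    def test_pure_noise_is_empty_result_error(self, rng):
        rec = PPGRecording(rng.normal(0, 1, 200 * 60), fs=200.0)
        with pytest.raises(BeatDetectionError):
            detect_beats(rec)

    def test_short_recording_rejected(self):
        rec = PPGRecording(np.sin(np.arange(200 * 5) / 200 * 2 * np.pi), fs=200.0)
        with pytest.raises(ValueError, match="10 s"):
            detect_beats(rec)

    def test_amplitude_series_tracks_known_envelope(self, modulated_recording):
        beats = detect_beats(modulated_recording)
        envelope = 1 + 0.2 * np.sin(2 * np.pi * 0.10 * beats.peak_time)
        r = np.corrcoef(beats.amplitude, envelope)[0, 1]
        assert r > 0.95


class TestVariabilitySeries:
    def test_constant_amplitudes_give_zero_series(self, clean_recording):
        beats = detect_beats(clean_recording)
        series = build_variability_series(beats, resample_rate=2.0)
        assert np.max(np.abs(series)) < 1e-6

    def test_modulated_series_peaks_at_modulation_frequency(self, modulated_recording):
        beats = detect_beats(modulated_recording)
        series = build_variability_series(beats, resample_rate=2.0)
        spec = estimate_psd(series, 2.0, segment_s=128)
        assert spec.freqs[np.argmax(spec.psd)] == pytest.approx(0.10, abs=0.02)

    def test_nyquist_below_hf_edge_rejected(self, clean_recording):
        beats = detect_beats(clean_recording)
        with pytest.raises(ValueError, match="resample_rate"):
            build_variability_series(beats, resample_rate=0.5)

    def test_too_few_beats_rejected(self, clean_recording):
        beats = detect_beats(clean_recording)
        few = type(beats)(
            **{
                k: getattr(beats, k)[:5]
                for k in (
                    "trough_time", "peak_time", "trough_value", "peak_value",
                    "amplitude", "beat_interval", "pulse_width_norm",
                )
            }
        )
        with pytest.raises(ValueError, match="beats"):
            build_variability_series(few)


class TestEstimatePsd:
    RATE = 2.0

    def test_parseval_pure_sine(self):
        t = np.arange(0, 600, 1 / self.RATE)
        a = 0.7
        series = a * np.sin(2 * np.pi * 0.1 * t)
        spec = estimate_psd(series, self.RATE, window="boxcar", detrend=False)
        power = np.trapezoid(spec.psd, spec.freqs)
        assert power == pytest.approx(a**2 / 2, rel=0.02)

    def test_parseval_white_noise(self, rng):
        v = 1.7
        series = rng.normal(0, math.sqrt(v), int(600 * self.RATE))
        spec = estimate_psd(series, self.RATE, window="boxcar", detrend=False)
        power = np.trapezoid(spec.psd, spec.freqs)
        assert power == pytest.approx(v, rel=0.10)

    def test_zero_series_gives_zero_psd(self):
        spec = estimate_psd(np.zeros(1200), self.RATE)
        assert np.all(spec.psd == 0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="segment"):
            estimate_psd(np.zeros(100), self.RATE, segment_s=128)


def _sine_spectrum(amps_freqs, rate=2.0, duration=600.0):
    t = np.arange(0, duration, 1 / rate)
    series = sum(a * np.sin(2 * np.pi * f * t) for f, a in amps_freqs)
    return estimate_psd(series, rate)


class TestSpectralFeatures:
    def test_hf_only_tone_gives_zero_lf(self):
        feats = spectral_features(_sine_spectrum([(0.30, 1.0)]))
        assert feats.lf_nu == pytest.approx(0.0, abs=1e-3)
        assert feats.mf_nu == pytest.approx(0.0, abs=1e-3)

    def test_equal_tones_give_unit_ratio(self):
        feats = spectral_features(_sine_spectrum([(0.10, 1.0), (0.30, 1.0)]))
        assert feats.lf_hf_ratio == pytest.approx(1.0, abs=0.05)

    @pytest.mark.parametrize("a, b", [(1.0, 2.0), (3.0, 1.0), (0.5, 0.4)])
    def test_ratio_follows_amplitude_squared(self, a, b):
        feats = spectral_features(_sine_spectrum([(0.10, a), (0.30, b)]))
        assert feats.lf_hf_ratio == pytest.approx(a**2 / b**2, rel=0.10)

    def test_mf_band_is_subset_of_lf(self):
        feats = spectral_features(_sine_spectrum([(0.10, 1.0), (0.05, 0.5), (0.3, 0.7)]))
        assert feats.mf_power <= feats.lf_power
        assert 0 <= feats.mf_nu <= feats.lf_nu <= 1

    def test_normalization_identity(self):
        feats = spectral_features(_sine_spectrum([(0.10, 1.0), (0.30, 0.5)]))
        hf_nu = feats.hf_power / (feats.lf_power + feats.hf_power)
        assert feats.lf_nu + hf_nu == pytest.approx(1.0, rel=1e-9)

    def test_band_additivity_with_aligned_edges(self):
        spec = _sine_spectrum([(0.10, 1.0), (0.30, 0.6)])
        from ppghemo.ppg_features import _band_power

        lf = _band_power(spec.freqs, spec.psd, 0.04, 0.145)
        hf = _band_power(spec.freqs, spec.psd, 0.145, 0.45)
        total = _band_power(spec.freqs, spec.psd, 0.04, 0.45)
        assert lf + hf == pytest.approx(total, rel=1e-9)

    def test_zero_hf_power_rejected(self):
        freqs = np.linspace(0.0, 0.5, 101)
        psd = np.where(freqs < 0.12, 1.0, 0.0)
        spec = VariabilitySpectrum(freqs, psd)
        with pytest.raises(ValueError, match="ratio undefined"):
            spectral_features(spec)

    def test_spectrum_must_cover_analysis_range(self):
        spec = VariabilitySpectrum(np.linspace(0.05, 0.4, 50), np.ones(50))
        with pytest.raises(ValueError, match="cover"):
            spectral_features(spec)


class TestEndToEnd:
    def test_extracted_ratio_monotone_in_true_ratio(self):
        ratios = []
        for d_lf, d_hf in [(0.04, 0.08), (0.06, 0.06), (0.08, 0.04)]:
            cfg = SynthPPGConfig(
                duration_s=600, fs=200, heart_rate_bpm=84, pulse_width_frac=0.3,
                am_components=((0.10, d_lf), (0.30, d_hf)),
                baseline_components=(), noise_sd=0.0, seed=1,
            )
            feats = extract_ppg_features(generate_ppg(cfg))
            ratios.append(feats["lf_hf"])
        assert ratios[0] < ratios[1] < ratios[2]
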
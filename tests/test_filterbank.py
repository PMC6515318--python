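"""Filtering and MAV feature extraction: frequency-response oracles via
FFT, brute-force window sums, and the band-list arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from distalemg.filterbank import (
    FilterBankSpec,
    PreprocessConfig,
    bandpass_filter,
    build_band_list,
    extract_distal_features,
    extract_target_envelopes,
    mav,
    notch_filter,
    window_samples,
)
from distalemg.signals import DISTAL_LABELS, MUSCLE_LABELS, ParameterError, SignalRecord

FS = 2000.0


def _sine(freq, n=8192, fs=FS):
    return np.sin(2 * np.pi * freq * np.arange(n) / fs)


class TestNotch:
    def test_mains_sinusoid_strongly_attenuated(self):
        rec = SignalRecord(_sine(50.0)[None, :], FS, ["x"])
        out = notch_filter(rec, 50.0, 30.0)
        rms_in = np.sqrt(np.mean(rec.samples**2))
        rms_out = np.sqrt(np.mean(out.samples**2))
        assert rms_out < 0.10 * rms_in

    def test_half_mains_sinusoid_passes(self):
        rec = SignalRecord(_sine(25.0)[None, :], FS, ["x"])
        out = notch_filter(rec, 50.0, 30.0)
        rms_in = np.sqrt(np.mean(rec.samples**2))
        rms_out = np.sqrt(np.mean(out.samples**2))
        assert abs(rms_out - rms_in) < 0.05 * rms_in

    def test_zero_in_zero_out(self):
        rec = SignalRecord(np.zeros((2, 500)), FS)
        assert np.allclose(notch_filter(rec, 50.0).samples, 0.0)

    def test_mains_at_or_above_nyquist_rejected(self):
        rec = SignalRecord(np.zeros((1, 100)), FS)
        with pytest.raises(ParameterError):
            notch_filter(rec, 1000.0)


class TestBandpass:
    def test_dc_offset_removed(self):
        out = bandpass_filter(np.full(4096, 3.7), 20, 500, FS)
        assert np.max(np.abs(out)) < 1e-3

    def test_in_band_amplitude_preserved(self):
        x = _sine(200.0)
        out = bandpass_filter(x, 20, 500, FS)
        # FFT gain oracle at the tone frequency
        gain = np.abs(np.fft.rfft(out)).max() / np.abs(np.fft.rfft(x)).max()
        assert abs(gain - 1.0) < 0.05

    def test_out_of_band_amplitude_reduced(self):
        x = _sine(10.0)  # low_hz / 2
        out = bandpass_filter(x, 20, 500, FS)
        gain = np.abs(np.fft.rfft(out)).max() / np.abs(np.fft.rfft(x)).max()
        assert gain < 0.10

    def test_zero_phase_preserves_burst_timing(self):
        # the energy centroid of a burst must not shift (no group delay)
        x = np.zeros(4096)
        x[2000:2100] = _sine(150.0, 100)
        out = bandpass_filter(x, 20, 500, FS)
        k = np.arange(x.size)
        centroid_in = np.sum(k * x**2) / np.sum(x**2)
        centroid_out = np.sum(k * out**2) / np.sum(out**2)
        assert abs(centroid_out - centroid_in) < 5

    def test_invalid_band_rejected(self):
        with pytest.raises(ParameterError):
            bandpass_filter(np.zeros(100), 500, 20, FS)
        with pytest.raises(ParameterError):
            bandpass_filter(np.zeros(100), 20, 1200, FS)

    def test_nyquist_collision_clipped_with_warning(self):
        x = np.random.default_rng(0).normal(size=4096)
        with pytest.warns(UserWarning, match="Nyquist"):
            out = bandpass_filter(x, 20, 500, 1000.0)
        assert out.shape == x.shape


class TestBandList:
    def test_defaults_give_35_bands(self):
        bands = build_band_list(FilterBankSpec())
        assert len(bands) == 35

    def test_band_endpoints(self):
        bands = build_band_list(FilterBankSpec())
        assert bands[0] == (20.0, 500.0)
        assert bands[1] == (20.0, 170.0)
        assert bands[-1] == (350.0, 500.0)

    def test_single_window_degenerate_case(self):
        spec = FilterBankSpec(window_width=480.0, step=480.0)
        assert len(build_band_list(spec)) == 2

    def test_all_windows_inside_search_range(self):
        spec = FilterBankSpec()
        for lo, hi in build_band_list(spec)[1:]:
            assert lo >= spec.search_low
            assert hi <= spec.search_high + 1e-9

    def test_invalid_spec_rejected(self):
        with pytest.raises(ParameterError):
            FilterBankSpec(step=0.0)
        with pytest.raises(ParameterError):
            FilterBankSpec(window_width=-5.0)


class TestMav:
    def test_constant_signal(self):
        assert np.allclose(mav(np.full(20, -3.0), 5), 3.0)

    def test_alternating_unit_signal(self):
        np.testing.assert_allclose(mav(np.array([1.0, -1.0, 1.0, -1.0]), 2), 1.0)

    def test_matches_double_loop_oracle(self, rng):
        x = rng.normal(size=50)
        tau = 7
        got = mav(x, tau)
        for k in range(50):
            lo = max(0, k - tau + 1)
            expected = sum(abs(x[j]) for j in range(lo, k + 1)) / (k - lo + 1)
            assert got[k] == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        scale=st.floats(-5, 5, allow_nan=False),
        tau=st.integers(1, 12),
        seed=st.integers(0, 10),
    )
    def test_scale_equivariance(self, scale, tau, seed):
        x = np.random.default_rng(seed).normal(size=40)
        np.testing.assert_allclose(
            mav(scale * x, tau), abs(scale) * mav(x, tau), atol=1e-12
        )

    def test_window_arithmetic(self):
        assert window_samples(2000.0, 0.1) == 200
        assert window_samples(1000.0, 0.1) == 100

    def test_invalid_window_rejected(self):
        with pytest.raises(ParameterError):
            mav(np.ones(10), 0)


class TestExtraction:
    def test_target_envelope_shape_and_window(self, short_recording):
        env = extract_target_envelopes(short_recording.target)
        assert env.values.shape == (6, short_recording.target.n_samples)
        assert env.tau == 200
        assert np.all(env.values >= 0)

    def test_target_row_order_follows_input_labels(self, short_recording):
        env = extract_target_envelopes(short_recording.target)
        assert env.labels == list(MUSCLE_LABELS)

    def test_zero_target_record_gives_zero_envelopes(self):
        rec = SignalRecord(np.zeros((6, 1000)), FS, list(MUSCLE_LABELS))
        env = extract_target_envelopes(rec)
        assert np.allclose(env.values, 0.0, atol=1e-9)

    def test_wrong_target_channel_count_rejected(self):
        rec = SignalRecord(np.zeros((4, 100)), FS)
        with pytest.raises(ParameterError):
            extract_target_envelopes(rec)

    def test_default_feature_count_is_175(self, short_recording):
        fm = extract_distal_features(short_recording.distal)
        assert fm.values.shape[0] == 5 * 35 == 175
        assert len(fm.row_labels) == 175
        assert fm.row_labels[0] == "A1_20-500Hz"

    def test_zero_distal_record_gives_zero_features(self):
        rec = SignalRecord(np.zeros((5, 1000)), FS, list(DISTAL_LABELS))
        fm = extract_distal_features(rec)
        assert np.allclose(fm.values, 0.0, atol=1e-9)

    def test_single_band_spec_reduces_to_baseline(self, short_recording):
        # one-band bank == notch -> 20-500 bandpass -> MAV per channel
        fm = extract_distal_features(
            short_recording.distal, FilterBankSpec.single_band((20.0, 500.0))
        )
        assert fm.values.shape[0] == 5
        pre = PreprocessConfig()
        clean = notch_filter(short_recording.distal, pre.mains_hz, pre.notch_quality)
        for j in range(5):
            banded = bandpass_filter(clean.samples[j], 20.0, 500.0, FS)
            np.testing.assert_allclose(fm.values[j], mav(banded, 200), atol=1e-12)

    def test_band_above_nyquist_names_the_band(self):
        rec = SignalRecord(np.zeros((5, 1000)), 600.0, list(DISTAL_LABELS))
        with pytest.raises(ParameterError, match="500"):
            extract_distal_features(rec)
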
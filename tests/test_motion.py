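"""Gait/tapping time-domain, spectral and tap-event features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qscreen.io import AccelerometerTrace, TapEventSeries
from qscreen.motion import (GAIT_FEATURES, TAP_FEATURES, gait_feature_block,
                            magnitude_series, spectrum_features,
                            tap_event_features, tapping_feature_block,
                            time_domain_stats)

from conftest import random_trace


def const_trace(x, y, z, n=16, fs=100.0):
    t = np.arange(n) / fs
    return AccelerometerTrace(t, np.full(n, x), np.full(n, y),
                              np.full(n, z), sample_rate_hz=fs)


class TestMagnitudeAndStats:
    def test_three_four_five(self):
        assert np.allclose(magnitude_series(const_trace(3, 4, 0)), 5.0)

    def test_zero_trace(self):
        assert np.all(magnitude_series(const_trace(0, 0, 0)) == 0)

    def test_magnitude_matches_brute_force(self, rng):
        tr = random_trace(7)
        expect = [np.sqrt(a * a + b * b + c * c)
                  for a, b, c in zip(tr.x, tr.y, tr.z)]
        np.testing.assert_allclose(magnitude_series(tr), expect, rtol=1e-12)

    def test_constant_axis(self):
        s = time_domain_stats(const_trace(3, 0, 0))
        assert s["rms_x"] == pytest.approx(3.0)
        assert s["std_x"] == pytest.approx(0.0)

    def test_alternating_axis_population_std(self):
        t = np.arange(4) / 100.0
        x = np.array([1.0, -1.0, 1.0, -1.0])
        tr = AccelerometerTrace(t, x, np.zeros(4), np.zeros(4), 100.0)
        s = time_domain_stats(tr)
        assert s["rms_x"] == pytest.approx(1.0)
        assert s["std_x"] == pytest.approx(1.0)  # divisor N, not N-1

    def test_stats_match_definitional_sums(self):
        tr = random_trace(11)
        s = time_domain_stats(tr)
        assert s["rms_y"] == pytest.approx(
            np.sqrt(sum(v * v for v in tr.y) / len(tr.y)), rel=1e-12)
        mean = sum(tr.y) / len(tr.y)
        assert s["std_y"] == pytest.approx(
            np.sqrt(sum((v - mean) ** 2 for v in tr.y) / len(tr.y)),
            rel=1e-12)


class TestSpectrumFeatures:
    def test_pure_sine_peaks_at_its_frequency(self):
        fs, n, f0 = 100.0, 1000, 5.0
        series = np.sin(2 * np.pi * f0 * np.arange(n) / fs)
        spec = spectrum_features(series, fs)
        bin_hz = fs / n
        assert abs(spec.dominant_frequency_hz - f0) <= bin_hz + 1e-12
        assert abs(spec.spectral_centroid_hz - f0) <= 0.2
        assert abs(spec.mean_frequency_hz - f0) <= 0.2

    def test_dc_only_series_degenerate(self):
        spec = spectrum_features(np.full(64, 3.0), 100.0)
        assert spec.degenerate
        assert spec.spectral_spread_hz == 0.0

    def test_two_equal_sines_centroid_and_spread(self):
        fs, n = 100.0, 2000
        t = np.arange(n) / fs
        series = np.sin(2 * np.pi * 2 * t) + np.sin(2 * np.pi * 8 * t)
        spec = spectrum_features(series, fs)
        # two equal lines at 2 and 8 Hz: centroid 5, spread 3
        assert spec.spectral_centroid_hz == pytest.approx(5.0, abs=0.2)
        assert spec.spectral_spread_hz == pytest.approx(3.0, abs=0.2)

    def test_needs_eight_samples(self):
        with pytest.raises(ValueError):
            spectrum_features(np.zeros(7), 100.0)


class TestTapEventFeatures:
    def test_uniform_alternation(self):
        taps = TapEventSeries(np.array([0.0, 0.2, 0.4, 0.6]),
                              ["left", "right", "left", "right"])
        f = tap_event_features(taps)
        assert (f["taps_left"], f["taps_right"], f["taps_total"]) == (2, 2, 4)
        assert f["taps_repeated"] == 0
        assert f["tap_consistency_s"] == pytest.approx(0.0)

    def test_repeat_and_consistency_by_hand(self):
        taps = TapEventSeries(np.array([0.0, 0.5, 1.5]),
                              ["left", "left", "right"])
        f = tap_event_features(taps)
        assert f["taps_repeated"] == 1
        # intervals [0.5, 1.0]: population std = 0.25
        assert f["tap_consistency_s"] == pytest.approx(0.25)

    def test_empty_series(self):
        f = tap_event_features(TapEventSeries(np.array([]), []))
        assert all(v == 0 for v in f.values())


class TestFeatureBlocks:
    def test_gait_block_names_and_degenerate_zero_trace(self):
        block = gait_feature_block(const_trace(0, 0, 0))
        assert set(block) == set(GAIT_FEATURES)
        assert all(v == 0.0 for v in block.values())

    def test_gait_block_matches_component_recomputation(self):
        tr = random_trace(23)
        block = gait_feature_block(tr)
        stats = time_domain_stats(tr)
        spec = spectrum_features(magnitude_series(tr), tr.sample_rate_hz)
        assert block["gait_rms_total"] == stats["rms_total"]
        assert block["gait_spectral_spread"] == spec.spectral_spread_hz

    def test_injected_tremor_frequency_recovered(self):
        fs, n, f_tremor = 100.0, 3000, 5.0
        t = np.arange(n) / fs
        z = 1.0 + 0.8 * np.sin(2 * np.pi * f_tremor * t)
        tr = AccelerometerTrace(t, np.zeros(n), np.zeros(n), z, fs)
        block = gait_feature_block(tr)
        assert abs(block["gait_dominant_frequency"] - f_tremor) <= fs / n

    def test_tapping_block_event_and_accel_parts(self):
        taps = TapEventSeries(np.array([0.1, 0.3, 0.5]),
                              ["left", "right", "left"])
        block = tapping_feature_block(taps, const_trace(0, 0, 0))
        assert set(block) == set(TAP_FEATURES)
        assert block["tap_taps_total"] == 3
        assert block["tap_rms_total"] == 0.0

    def test_short_trace_spectrum_degenerate_but_events_fine(self):
        taps = TapEventSeries(np.array([0.1, 0.2]), ["left", "right"])
        block = tapping_feature_block(taps, const_trace(1, 1, 1, n=4))
        assert block["tap_taps_total"] == 2
        assert block["tap_dominant_frequency"] == 0.0
        assert block["tap_rms_x"] == pytest.approx(1.0)


class TestInvariances:
    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(0.1, 50.0), seed=st.integers(0, 100))
    def test_scale_covariance(self, scale, seed):
        tr = random_trace(seed, n=128)
        scaled = AccelerometerTrace(tr.timestamps, scale * tr.x,
                                    scale * tr.y, scale * tr.z,
                                    tr.sample_rate_hz)
        b1, b2 = gait_feature_block(tr), gait_feature_block(scaled)
        for k in b1:
            # every Hz-valued feature (including spread: the amplitude
            # weights cancel between numerator and denominator) is
            # invariant; rms/std features scale linearly
            if "frequency" in k or "centroid" in k or "spread" in k:
                assert b2[k] == pytest.approx(b1[k], rel=1e-9)
            else:
                assert b2[k] == pytest.approx(scale * b1[k], rel=1e-9)

    def test_time_shift_invariance(self):
        tr = random_trace(5, n=128)
        shifted = AccelerometerTrace(tr.timestamps + 100.0, tr.x, tr.y,
                                     tr.z, tr.sample_rate_hz)
        assert gait_feature_block(tr) == gait_feature_block(shifted)

    def test_spread_nonnegative_single_bin_zero(self):
        fs, n = 100.0, 1024
        series = np.sin(2 * np.pi * (fs / n) * 8 * np.arange(n) / fs)
        spec = spectrum_features(series, fs)
        assert spec.spectral_spread_hz >= 0
        # a bin-centred sinusoid concentrates all mass in one bin
        assert spec.spectral_spread_hz < 0.05
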
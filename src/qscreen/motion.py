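"""Gait and tapping feature extraction.

Time-domain statistics (per-axis and total-magnitude RMS and standard
deviation), FFT-domain spectral summaries of the acceleration magnitude
(dominant frequency, power-weighted mean frequency, amplitude-weighted
spectral centroid and spread), and tap-event dexterity/consistency
measures.  Tremor in the 4-6 Hz band and erratic, inconsistent movement
are the disease signatures these features are designed to pick up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AccelerometerTrace, TapEventSeries

GAIT_FEATURES = (
    "gait_rms_x", "gait_rms_y", "gait_rms_z", "gait_rms_total",
    "gait_std_x", "gait_std_y", "gait_std_z", "gait_std_total",
    "gait_dominant_frequency", "gait_mean_frequency",
    "gait_spectral_centroid", "gait_spectral_spread",
)
TAP_FEATURES = (
    "tap_taps_left", "tap_taps_right", "tap_taps_total", "tap_taps_repeated",
    "tap_consistency_s",
    "tap_rms_x", "tap_rms_y", "tap_rms_z", "tap_rms_total",
    "tap_std_x", "tap_std_y", "tap_std_z", "tap_std_total",
    "tap_dominant_frequency", "tap_mean_frequency",
    "tap_spectral_centroid", "tap_spectral_spread",
)


@dataclass
class SpectrumSummary:
    dominant_frequency_hz: float
    mean_frequency_hz: float
    spectral_centroid_hz: float
    spectral_spread_hz: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            for v in (self.dominant_frequency_hz, self.mean_frequency_hz,
                      self.spectral_centroid_hz, self.spectral_spread_hz):
                if v < 0:
                    raise ValueError("spectral summary values must be >= 0")


def magnitude_series(trace: AccelerometerTrace) -> np.ndarray:
    """Per-sample Euclidean magnitude sqrt(x^2 + y^2 + z^2)."""
    return np.sqrt(trace.x ** 2 + trace.y ** 2 + trace.z ** 2)


def time_domain_stats(trace: AccelerometerTrace) -> dict[str, float]:
    """RMS and population standard deviation per axis and of the magnitude."""
    mag = magnitude_series(trace)
    out = {}
    for name, arr in (("x", trace.x), ("y", trace.y),
                      ("z", trace.z), ("total", mag)):
        out[f"rms_{name}"] = float(np.sqrt(np.mean(arr ** 2)))
        out[f"std_{name}"] = float(np.std(arr))  # divisor N
    return out


def spectrum_features(series: np.ndarray,
                      sample_rate_hz: float) -> SpectrumSummary:
    """Spectral summary of a uniform series via the one-sided FFT amplitude.

    The DC bin is excluded first: the gravity offset dominates raw
    accelerometer magnitude and carries no movement information.
    dominant = argmax amplitude; centroid = amplitude-weighted mean
    frequency; mean frequency = power (A^2) weighted mean; spread =
    amplitude-weighted standard deviation about the centroid.
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 8:
        raise ValueError("spectrum_features needs >= 8 samples")
    if not np.all(np.isfinite(series)):
        raise ValueError("non-finite values in series")
    amp = np.abs(np.fft.rfft(series))[1:]
    freqs = np.fft.rfftfreq(len(series), d=1.0 / sample_rate_hz)[1:]
    total = amp.sum()
    if total <= 0 or not total > 1e-300:
        return SpectrumSummary(0.0, 0.0, 0.0, 0.0, degenerate=True)
    dominant = float(freqs[np.argmax(amp)])
    centroid = float(np.sum(freqs * amp) / total)
    power = amp ** 2
    mean_freq = float(np.sum(freqs * power) / np.sum(power))
    spread = float(np.sqrt(np.sum((freqs - centroid) ** 2 * amp) / total))
    return SpectrumSummary(dominant, mean_freq, centroid, spread)


def tap_event_features(taps: TapEventSeries) -> dict[str, float]:
    """Counts by button, consecutive same-button repeats, and tap consistency.

    ``taps_repeated`` counts consecutive event pairs on the same button (a
    failure to alternate); ``tap_consistency_s`` is the population standard
    deviation of successive inter-tap intervals (0 when fewer than 3 taps).
    """
    buttons = taps.buttons
    n = len(buttons)
    left = sum(b == "left" for b in buttons)
    right = n - left
    repeated = sum(buttons[i] == buttons[i + 1] for i in range(n - 1))
    if n >= 3:
        intervals = np.diff(taps.times)
        consistency = float(np.std(intervals))
    else:
        consistency = 0.0
    return {
        "taps_left": float(left),
        "taps_right": float(right),
        "taps_total": float(n),
        "taps_repeated": float(repeated),
        "tap_consistency_s": consistency,
    }


def _accel_features(trace: AccelerometerTrace) -> dict[str, float]:
    feats = time_domain_stats(trace)
    mag = magnitude_series(trace)
    if len(mag) >= 8:
        spec = spectrum_features(mag, trace.sample_rate_hz)
    else:
        spec = SpectrumSummary(0.0, 0.0, 0.0, 0.0, degenerate=True)
    feats["dominant_frequency"] = spec.dominant_frequency_hz
    feats["mean_frequency"] = spec.mean_frequency_hz
    feats["spectral_centroid"] = spec.spectral_centroid_hz
    feats["spectral_spread"] = spec.spectral_spread_hz
    feats["_degenerate_spectrum"] = float(spec.degenerate)
    return feats


def gait_feature_block(trace: AccelerometerTrace) -> dict[str, float]:
    """The 12 gait features, names prefixed ``gait_``."""
    feats = _accel_features(trace)
    out = {f"gait_{k}": v for k, v in feats.items() if not k.startswith("_")}
    assert set(out) == set(GAIT_FEATURES)
    return out


def tapping_feature_block(taps: TapEventSeries,
                          trace: AccelerometerTrace) -> dict[str, float]:
    """The 17 tapping features (5 event + 12 accelerometer), prefixed ``tap_``."""
    out = {}
    ev = tap_event_features(taps)
    out.update({f"tap_{k}" if not k.startswith("tap_") else k: v
                for k, v in ev.items()})
    acc = _accel_features(trace)
    out.update({f"tap_{k}": v for k, v in acc.items()
                if not k.startswith("_")})
    assert set(out) == set(TAP_FEATURES)
    return out
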
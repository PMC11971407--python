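"""Shared fixtures: synthetic signals and small cohorts, all seeded."""

import io
import wave

import numpy as np
import pytest

from qscreen.io import AccelerometerTrace, AudioClip


def make_wav_bytes(samples: np.ndarray, fs: int = 16000,
                   n_channels: int = 1) -> bytes:
    """16-bit PCM WAV bytes from float samples in [-1, 1]."""
    pcm = np.clip(np.round(np.asarray(samples) * 32768.0),
                  -32768, 32767).astype("<i2")
    buf = io.BytesIO()
    with wave.open(buf, "wb") as wf:
        wf.setnchannels(n_channels)
        wf.setsampwidth(2)
        wf.setframerate(fs)
        wf.writeframes(pcm.tobytes())
    return buf.getvalue()


def harmonic_tone(f0: float, duration_s: float = 2.0, fs: int = 16000,
                  n_harmonics: int = 25, amp: float = 0.5) -> AudioClip:
    """Rich periodic tone with 1/k harmonic rolloff (pulse-like source)."""
    t = np.arange(int(duration_s * fs)) / fs
    x = sum((1.0 / k) * np.sin(2 * np.pi * f0 * k * t)
            for k in range(1, n_harmonics + 1))
    return AudioClip(amp * x / np.max(np.abs(x)), fs)


def random_trace(seed: int, n: int = 256, fs: float = 100.0
                 ) -> AccelerometerTrace:
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    return AccelerometerTrace(t, rng.standard_normal(n),
                             rng.standard_normal(n),
                             rng.standard_normal(n), sample_rate_hz=fs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact but well-separated synthetic cohort for pipeline tests."""
    from qscreen.synth import synth_cohort

    return synth_cohort(n=40, seed=101, voice_duration_s=2.0,
                        gait_duration_s=10.0)


@pytest.fixture(scope="session")
def small_feature_table(small_cohort):
    from qscreen.workflow import extract_cohort_features

    cohort, data, _ = small_cohort
    return extract_cohort_features(cohort, data)
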
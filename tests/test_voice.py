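"""Sustained-phonation feature extraction: pitch, descriptors,
perturbation/periodicity measures, breathiness components, MFCC-PCA."""

import numpy as np
import pytest

from qscreen.io import AudioClip
from qscreen.voice import (DEFAULT_ABI_COEFFICIENTS, MfccPca, abi_score,
                           cpp_smoothed_db, frame_descriptors, frame_signal,
                           gne_ratio, hnr_db, mfcc_summary, pitch_track,
                           shimmer_db, spectral_noise_measures,
                           voice_feature_block)

from conftest import harmonic_tone

FS = 16000


def white_noise(duration_s=2.0, fs=FS, seed=0, amp=0.3):
    rng = np.random.default_rng(seed)
    return AudioClip(amp * rng.standard_normal(int(duration_s * fs)), fs)


def jittered_tone(f0, jitter_pct, duration_s=2.0, fs=FS, seed=0,
                  n_harmonics=6, shimmer_db_inject=0.0, noise_amp=0.0):
    """Cycle-level synthesis independent of the package generator."""
    rng = np.random.default_rng(seed)
    t0 = 1.0 / f0
    n_total = int(duration_s * fs)
    n_cycles = int(duration_s * f0 * 1.3) + 4
    periods = t0 * (1 + jitter_pct / 100 * rng.standard_normal(n_cycles))
    amps = 10 ** (shimmer_db_inject * np.sqrt(np.pi) / 2
                  * rng.standard_normal(n_cycles) / 20)
    counts = np.maximum(np.diff(np.concatenate(
        [[0], np.round(np.cumsum(periods) * fs).astype(int)])), 1)
    inst_f = np.repeat(1 / periods, counts)[:n_total]
    phase = 2 * np.pi * np.cumsum(inst_f) / fs
    cyc = np.minimum(np.floor(phase / (2 * np.pi) + 0.5).astype(int),
                     n_cycles - 1)
    inst_a = amps[cyc]
    x = sum((1 / k) * np.sin(k * phase) for k in range(1, n_harmonics + 1))
    x = inst_a * x
    if noise_amp:
        x = x + noise_amp * rng.standard_normal(n_total)
    return AudioClip(0.6 * x / np.max(np.abs(x)), fs)


class TestFraming:
    def test_frame_count_one_second(self):
        clip = AudioClip(np.zeros(FS), FS)
        grid = frame_signal(clip, 0.040, 0.010)
        assert grid.n_frames == 97  # floor((1000-40)/10)+1

    def test_exactly_one_frame(self):
        clip = AudioClip(np.zeros(int(0.040 * FS)), FS)
        assert frame_signal(clip).n_frames == 1

    def test_too_short_clip_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            frame_signal(AudioClip(np.zeros(int(0.020 * FS)), FS))


class TestPitch:
    def test_harmonic_tone_pitch_recovered(self):
        track = pitch_track(frame_signal(harmonic_tone(150.0)))
        mean, std = track.stats()
        assert mean == pytest.approx(150.0, abs=2.0)
        assert std < 2.0

    def test_white_noise_unvoiced(self):
        track = pitch_track(frame_signal(white_noise()))
        assert not track.any_voiced

    def test_jitter_raises_pitch_spread(self):
        clean = pitch_track(frame_signal(jittered_tone(150, 0.0)))
        jit = pitch_track(frame_signal(jittered_tone(150, 2.0)))
        m, s = jit.stats()
        assert m == pytest.approx(150.0, abs=3.0)
        assert s > clean.stats()[1]


class TestFrameDescriptors:
    def test_pure_tone_reference_values(self):
        t = np.arange(2 * FS) / FS
        clip = AudioClip(0.5 * np.sin(2 * np.pi * 1000 * t), FS)
        grid = frame_signal(clip)
        d = frame_descriptors(grid)
        assert d["zcr_mean"] == pytest.approx(2000.0, rel=0.02)
        assert d["spectral_centroid_mean"] == pytest.approx(1000.0, abs=20)
        bin_hz = FS / grid.frame_len
        assert abs(d["spectral_rolloff_mean"] - 1000.0) <= bin_hz

    def test_silence_all_zero(self):
        d = frame_descriptors(frame_signal(AudioClip(np.zeros(FS), FS)))
        assert all(v == 0.0 for v in d.values())

    def test_amplitude_doubling(self):
        clip = harmonic_tone(180.0)
        double = AudioClip(np.clip(2 * clip.samples, -1, 1),
                           clip.sample_rate_hz)
        d1 = frame_descriptors(frame_signal(clip))
        d2 = frame_descriptors(frame_signal(double))
        assert d2["volume_mean"] == pytest.approx(2 * d1["volume_mean"],
                                                  rel=1e-6)
        for k in ("zcr_mean", "spectral_centroid_mean",
                  "spectral_bandwidth_mean", "spectral_rolloff_mean"):
            assert d2[k] == pytest.approx(d1[k], rel=1e-6)


class TestShimmer:
    def test_periodic_tone_near_zero(self):
        clip = harmonic_tone(150.0)
        track = pitch_track(frame_signal(clip))
        assert shimmer_db(clip, track) == pytest.approx(0.0, abs=0.1)

    def test_alternating_amplitudes_closed_form(self):
        # cycles alternating A and 2A: every ratio is 2 -> 6.02 dB
        fs, f0 = FS, 160.0
        period = int(round(fs / f0))
        n_cycles = 200
        x = []
        for i in range(n_cycles):
            amp = 1.0 if i % 2 == 0 else 2.0
            x.append(amp * np.sin(2 * np.pi * np.arange(period) / period))
        clip = AudioClip(0.4 * np.concatenate(x), fs)
        # constrain the search range to the nominal cycle rate: amplitude
        # alternation doubles the true period, which is not the cycle
        # structure shimmer is defined over
        track = pitch_track(frame_signal(clip), f_min=100.0)
        assert shimmer_db(clip, track) == pytest.approx(
            20 * np.log10(2), abs=0.4)

    def test_injected_shimmer_recovered(self):
        clip = jittered_tone(150, 0.2, shimmer_db_inject=1.0, seed=4)
        track = pitch_track(frame_signal(clip))
        assert shimmer_db(clip, track) == pytest.approx(1.0, abs=0.3)

    def test_unvoiced_clip_missing(self):
        clip = white_noise()
        track = pitch_track(frame_signal(clip))
        assert np.isnan(shimmer_db(clip, track))


class TestHnr:
    def test_clean_tone_high(self):
        grid = frame_signal(harmonic_tone(150.0))
        assert hnr_db(grid, pitch_track(grid)) >= 30.0

    def test_equal_power_noise_near_zero(self):
        tone = harmonic_tone(150.0, amp=0.4)
        p_tone = np.mean(tone.samples ** 2)
        rng = np.random.default_rng(8)
        noisy = AudioClip(tone.samples + np.sqrt(p_tone)
                          * rng.standard_normal(len(tone.samples)),
                          tone.sample_rate_hz)
        grid = frame_signal(noisy)
        assert hnr_db(grid, pitch_track(grid)) == pytest.approx(0.0, abs=1.5)

    def test_noise_only_missing(self):
        grid = frame_signal(white_noise())
        assert np.isnan(hnr_db(grid, pitch_track(grid)))


class TestCppAndGne:
    def test_periodic_beats_noise_by_margin(self):
        cpp_tone = cpp_smoothed_db(harmonic_tone(150.0))
        cpp_noise = cpp_smoothed_db(white_noise())
        assert cpp_tone - cpp_noise >= 5.0

    def test_cpp_amplitude_invariant(self):
        clip = harmonic_tone(200.0, amp=0.05)
        loud = AudioClip(10 * clip.samples, clip.sample_rate_hz)
        assert cpp_smoothed_db(loud) == pytest.approx(
            cpp_smoothed_db(clip), abs=0.1)

    def test_gne_pulsed_high_noise_lower(self):
        g_pulsed = gne_ratio(harmonic_tone(150.0))
        g_noise = gne_ratio(white_noise())
        assert g_pulsed > 0.8
        assert g_noise < g_pulsed

    def test_gne_deterministic(self):
        clip = harmonic_tone(170.0)
        assert gne_ratio(clip) == gne_ratio(clip)


class TestSpectralNoiseMeasures:
    def test_h1_h2_closed_form(self):
        t = np.arange(4 * FS) / FS
        x = 0.4 * np.sin(2 * np.pi * 150 * t) \
            + 0.2 * np.sin(2 * np.pi * 300 * t)
        clip = AudioClip(x, FS)
        track = pitch_track(frame_signal(clip))
        m = spectral_noise_measures(clip, track)
        assert m["h1_h2_db"] == pytest.approx(20 * np.log10(2), abs=0.3)

    def test_tone_has_no_hf_noise(self):
        t = np.arange(2 * FS) / FS
        clip = AudioClip(0.5 * np.sin(2 * np.pi * 1000 * t), FS)
        m = spectral_noise_measures(clip, pitch_track(frame_signal(clip)))
        assert m["hf_noise_6000"] == pytest.approx(0.0, abs=1e-3)

    def test_white_noise_hf_fraction(self):
        clip = white_noise(duration_s=4.0, seed=2)
        m = spectral_noise_measures(clip, pitch_track(frame_signal(clip)))
        # flat spectrum: (8000-6000)/8000 of the energy sits above 6 kHz
        assert m["hf_noise_6000"] == pytest.approx(0.25, abs=0.03)

    def test_low_rate_cannot_observe_6khz(self):
        clip = AudioClip(np.random.default_rng(0).standard_normal(8000),
                         8000)
        m = spectral_noise_measures(clip, pitch_track(frame_signal(clip)))
        assert np.isnan(m["hf_noise_6000"])


class TestAbi:
    COMPONENTS = {"cpp_smoothed_db": 10.0, "hnr_db": 20.0,
                  "shimmer_db": 0.5, "gne_ratio": 0.9, "h1_h2_db": 3.0,
                  "hf_noise_6000": 0.01, "psd_summary": 15.0}

    def test_intercept_only(self):
        coeff = {k: 0.0 for k in DEFAULT_ABI_COEFFICIENTS}
        coeff["intercept"] = 1.0
        assert abi_score(self.COMPONENTS, coeff) == 1.0

    def test_matches_hand_dot_product(self):
        expected = DEFAULT_ABI_COEFFICIENTS["intercept"] + sum(
            DEFAULT_ABI_COEFFICIENTS[k] * v
            for k, v in self.COMPONENTS.items())
        assert abi_score(self.COMPONENTS) == pytest.approx(expected,
                                                           rel=1e-12)

    def test_missing_component_gives_missing_index(self):
        comps = dict(self.COMPONENTS)
        comps["hnr_db"] = float("nan")
        assert np.isnan(abi_score(comps))


class TestMfccPca:
    def test_low_rank_training_zero_padded(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((2, 26))
        train = rng.standard_normal((30, 2)) @ base  # rank 2
        with pytest.warns(UserWarning, match="rank"):
            pca = MfccPca().fit(train)
        proj = pca.transform(train)
        assert proj.shape == (30, 10)
        assert np.allclose(proj[:, 2:], 0.0)

    def test_training_mean_maps_to_origin(self):
        rng = np.random.default_rng(1)
        train = rng.standard_normal((40, 26))
        pca = MfccPca().fit(train)
        assert np.allclose(pca.transform(train.mean(axis=0)[None, :]), 0.0,
                           atol=1e-10)

    def test_full_component_reconstruction(self):
        rng = np.random.default_rng(2)
        train = rng.standard_normal((40, 26))
        pca = MfccPca(n_components=26).fit(train)
        proj = pca.transform(train)
        recon = proj @ pca.components_ + pca.mean_
        np.testing.assert_allclose(recon, train, atol=1e-8)

    def test_mfcc_summary_shape(self):
        assert mfcc_summary(harmonic_tone(150.0)).shape == (26,)


class TestVoiceBlockInvariants:
    def test_gain_invariance_of_dimensionless_measures(self):
        clip = jittered_tone(160, 0.5, shimmer_db_inject=0.5,
                             noise_amp=0.01, seed=3)
        scaled = AudioClip(0.25 * clip.samples, clip.sample_rate_hz)
        b1 = voice_feature_block(clip)
        b2 = voice_feature_block(scaled)
        for k in ("voice_pitch_mean_hz", "voice_zcr_mean",
                  "voice_spectral_centroid_mean",
                  "voice_spectral_bandwidth_mean",
                  "voice_spectral_rolloff_mean", "voice_shimmer_db",
                  "voice_hnr_db", "voice_cpp_db", "voice_gne",
                  "voice_h1_h2_db", "voice_hf_noise_6000"):
            assert b2[k] == pytest.approx(b1[k], abs=0.1, rel=0.01), k
        assert b2["voice_volume_mean"] == pytest.approx(
            0.25 * b1["voice_volume_mean"], rel=1e-6)

    def test_monotone_degradation_under_noise(self):
        hnrs, cpps = [], []
        for noise_amp in (0.0, 0.05, 0.2):
            clip = jittered_tone(170, 0.3, noise_amp=noise_amp, seed=9)
            grid = frame_signal(clip)
            track = pitch_track(grid)
            hnrs.append(hnr_db(grid, track))
            cpps.append(cpp_smoothed_db(clip))
        assert hnrs[0] > hnrs[1] > hnrs[2]
        assert cpps[0] > cpps[1] > cpps[2]
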
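"""Seeded class-conditional synthetic cohort generation.

Emulates an mPower-style study: demographics drawn to match the source
cohort's age-band and smoking marginals, walking accelerometer traces
with an optional 4-6 Hz tremor component, alternating-button tap streams
with class-specific slowing and variability, and sustained-phonation
audio with controllable jitter, shimmer and harmonics-to-noise ratio.
Every generated participant stores its ground-truth generative
parameters so extractor-recovery tests can close the loop.

Effect magnitudes are explicit design parameters of the generator, not
estimates of the real cohort's distributions: the defaults give a
moderately separable two-class problem with the directionality the
disease implies (slower, more variable tapping; tremor band power; a
breathier, less harmonic voice; higher age).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (AccelerometerTrace, AudioClip, CohortTable,
                 ParticipantRecord, TapEventSeries, assemble_cohort)

# Age-band totals of the emulated cohort: (<40, 40-60, >60) out of 194,
# with 59/194 smokers.  The class-conditional band probabilities below
# average (under the 50/50 label mix) to those totals while making
# P(PD | band) increase with age.
AGE_BAND_TOTALS = (34, 60, 100)
N_REFERENCE = 194
SMOKER_TOTAL = 59
_BAND_TARGET = np.array(AGE_BAND_TOTALS) / N_REFERENCE
BAND_P_CONTROL = np.array([0.25, 0.35, 0.40])
BAND_P_PD = 2 * _BAND_TARGET - BAND_P_CONTROL
BAND_AGE_RANGES = ((20, 39), (40, 60), (61, 88))


@dataclass(frozen=True)
class ClassEffectProfile:
    """Generative parameters for one diagnosis class."""

    label: str
    # gait
    walk_frequency_hz: float = 2.0
    walk_amplitude: float = 1.0
    tremor_frequency_range: tuple[float, float] | None = None  # PD: (4, 6)
    tremor_amplitude: float = 0.0        # fraction of walk amplitude
    gait_noise: float = 0.05
    # tapping
    tap_interval_mean_s: float = 0.18
    tap_interval_cv: float = 0.10
    repeat_tap_probability: float = 0.02
    # voice
    jitter_pct: float = 0.3
    shimmer_db: float = 0.3
    hnr_target_db: float = 25.0
    f0_range_male: tuple[float, float] = (100.0, 130.0)
    f0_range_female: tuple[float, float] = (180.0, 220.0)

    def validate_against(self, control: "ClassEffectProfile") -> None:
        """PD must be no better than control in every configured dimension."""
        checks = [
            self.tremor_amplitude >= control.tremor_amplitude,
            self.tap_interval_mean_s >= control.tap_interval_mean_s,
            self.tap_interval_cv >= control.tap_interval_cv,
            self.repeat_tap_probability >= control.repeat_tap_probability,
            self.jitter_pct >= control.jitter_pct,
            self.shimmer_db >= control.shimmer_db,
            self.hnr_target_db <= control.hnr_target_db,
        ]
        if not all(checks):
            raise ValueError("PD profile must be uniformly 'worse' than "
                             "the control profile")


CONTROL_PROFILE = ClassEffectProfile(label="control")
PD_PROFILE = ClassEffectProfile(
    label="PD",
    tremor_frequency_range=(4.0, 6.0),
    tremor_amplitude=0.8,
    tap_interval_mean_s=0.35,
    tap_interval_cv=0.35,
    repeat_tap_probability=0.15,
    jitter_pct=1.5,
    shimmer_db=1.2,
    hnr_target_db=12.0,
)
PD_PROFILE.validate_against(CONTROL_PROFILE)


def null_profiles() -> tuple[ClassEffectProfile, ClassEffectProfile]:
    """Identical generative parameters for both labels (chance-level task)."""
    return CONTROL_PROFILE, replace(CONTROL_PROFILE, label="PD")


@dataclass
class SyntheticParticipant:
    record: ParticipantRecord
    gait: AccelerometerTrace
    taps: TapEventSeries
    tap_accel: AccelerometerTrace
    voice: AudioClip
    ground_truth: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Demographics
# ---------------------------------------------------------------------------

def synth_demographics(n: int, seed: int,
                       band_totals: tuple[int, int, int] = AGE_BAND_TOTALS,
                       smoker_total: int = SMOKER_TOTAL,
                       n_reference: int = N_REFERENCE
                       ) -> list[ParticipantRecord]:
    """Draw n participants with balanced labels and realistic marginals.

    Labels alternate to an exact balance; age bands are drawn from
    class-conditional distributions whose 50/50 mixture matches the
    reference band totals, which makes P(PD | band) increase with age.
    """
    totals = np.asarray(band_totals, dtype=float)
    if totals.sum() != n_reference or (totals < 0).any():
        raise ValueError("band totals must be non-negative and sum to the "
                         "reference cohort size")
    target = totals / n_reference
    p_pd = 2 * target - BAND_P_CONTROL
    if (p_pd < 0).any():
        raise ValueError("band totals incompatible with the control mixture")
    rng = np.random.default_rng(seed)
    p_smoker = smoker_total / n_reference
    records = []
    for i in range(n):
        label = "PD" if i % 2 == 0 else "control"
        p_band = p_pd if label == "PD" else BAND_P_CONTROL
        band = int(rng.choice(3, p=p_band))
        lo, hi = BAND_AGE_RANGES[band]
        age = float(rng.integers(lo, hi + 1))
        records.append(ParticipantRecord(
            participant_id=f"synth-{i:04d}",
            age=age,
            gender="female" if rng.random() < 0.5 else "male",
            smoker=bool(rng.random() < p_smoker),
            label=label,
            trial_refs={a: [f"synth-{i:04d}/{a}"]
                        for a in ("gait", "tapping", "voice")},
        ))
    return records


# ---------------------------------------------------------------------------
# Gait
# ---------------------------------------------------------------------------

def synth_gait(profile: ClassEffectProfile, duration_s: float = 30.0,
               fs: float = 100.0, seed: int = 0
               ) -> tuple[AccelerometerTrace, dict]:
    """Walking oscillation (fundamental + first harmonic) plus noise and,
    for the disease profile, a tremor sinusoid in the configured band."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration_s * fs)) / fs
    f_walk = profile.walk_frequency_hz
    amp = profile.walk_amplitude
    phase = rng.uniform(0, 2 * np.pi)
    z = (amp * np.sin(2 * np.pi * f_walk * t + phase)
         + 0.3 * amp * np.sin(2 * np.pi * 2 * f_walk * t + 2 * phase))
    truth = {"walk_frequency_hz": f_walk, "tremor_frequency_hz": None}
    if profile.tremor_frequency_range is not None \
            and profile.tremor_amplitude > 0:
        f_tremor = rng.uniform(*profile.tremor_frequency_range)
        z = z + profile.tremor_amplitude * amp * np.sin(
            2 * np.pi * f_tremor * t + rng.uniform(0, 2 * np.pi))
        truth["tremor_frequency_hz"] = float(f_tremor)
    x = 0.4 * z + profile.gait_noise * rng.standard_normal(len(t))
    y = 0.3 * z + profile.gait_noise * rng.standard_normal(len(t))
    # 1 g gravity offset on the vertical axis: keeps the magnitude series
    # linear in the oscillation instead of rectifying it (which would
    # double every spectral frequency)
    z = 1.0 + z + profile.gait_noise * rng.standard_normal(len(t))
    trace = AccelerometerTrace(t, x, y, z, sample_rate_hz=fs,
                               source_activity="gait")
    return trace, truth


# ---------------------------------------------------------------------------
# Tapping
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    sigma2 = np.log(1.0 + cv ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def synth_taps(profile: ClassEffectProfile, window_seconds: float = 20.0,
               fs: float = 100.0, seed: int = 0
               ) -> tuple[TapEventSeries, AccelerometerTrace, dict]:
    """Alternating taps with lognormal inter-tap intervals and an
    accelerometer trace carrying a transient at each tap.

    Lognormal intervals keep times positive with the right skew real
    tapping shows.  Each event repeats the previous button with the
    profile's repeat probability (an alternation failure).
    """
    rng = np.random.default_rng(seed)
    mu, sigma = _lognormal_params(profile.tap_interval_mean_s,
                                  profile.tap_interval_cv)
    times, buttons = [], []
    t = float(rng.lognormal(mu, sigma))
    current = "left" if rng.random() < 0.5 else "right"
    while t <= window_seconds:
        times.append(t)
        buttons.append(current)
        if rng.random() >= profile.repeat_tap_probability:
            current = "right" if current == "left" else "left"
        t += float(rng.lognormal(mu, sigma))
    taps = TapEventSeries(np.array(times), buttons,
                          window_seconds=window_seconds)

    # accelerometer: baseline noise + decaying 8 Hz transient per tap
    n = int(window_seconds * fs)
    tgrid = np.arange(n) / fs
    z = 0.02 * rng.standard_normal(n)
    for tt in times:
        idx = int(tt * fs)
        dur = min(int(0.15 * fs), n - idx)
        if dur <= 0:
            continue
        tau = np.arange(dur) / fs
        z[idx:idx + dur] += 0.5 * np.exp(-tau / 0.04) * np.sin(
            2 * np.pi * 8.0 * tau)
    if profile.tremor_frequency_range is not None \
            and profile.tremor_amplitude > 0:
        f_tremor = rng.uniform(*profile.tremor_frequency_range)
        z = z + 0.2 * profile.tremor_amplitude * np.sin(
            2 * np.pi * f_tremor * tgrid)
    x = 0.4 * z + 0.02 * rng.standard_normal(n)
    y = 0.3 * z + 0.02 * rng.standard_normal(n)
    z = 1.0 + z  # gravity offset, as in the gait trace
    trace = AccelerometerTrace(tgrid, x, y, z, sample_rate_hz=fs,
                               source_activity="tapping")
    truth = {
        "tap_interval_mean_s": profile.tap_interval_mean_s,
        "tap_interval_cv": profile.tap_interval_cv,
        "repeat_tap_probability": profile.repeat_tap_probability,
        "n_taps": len(times),
    }
    return taps, trace, truth


# ---------------------------------------------------------------------------
# Voice
# ---------------------------------------------------------------------------

def synth_voice(profile: ClassEffectProfile, gender: str = "female",
                duration_s: float = 10.0, fs: int = 16000, seed: int = 0,
                n_harmonics: int = 6) -> tuple[AudioClip, dict]:
    """Sustained-phonation synthesis: harmonic source with per-cycle jitter
    and shimmer, plus white noise scaled to a target HNR.

    Harmonic amplitudes roll off as 1/k.  Jitter perturbs each cycle's
    period by the given percentage (Gaussian); shimmer perturbs each
    cycle's amplitude in dB.  The additive noise power is set from the
    harmonic power so that 10 log10(P_harm / P_noise) equals the target.
    """
    rng = np.random.default_rng(seed)
    lo, hi = (profile.f0_range_female if gender == "female"
              else profile.f0_range_male)
    f0 = float(rng.uniform(lo, hi))
    t0 = 1.0 / f0
    n_total = int(duration_s * fs)

    # enough cycles to cover the clip even with jitter
    n_cycles = int(np.ceil(duration_s * f0 * 1.2)) + 4
    periods = t0 * (1.0 + (profile.jitter_pct / 100.0)
                    * rng.standard_normal(n_cycles))
    periods = np.clip(periods, 0.2 * t0, 5.0 * t0)
    # sqrt(pi)/2 scaling: consecutive cycle amplitudes then differ by the
    # requested shimmer value in expectation, E|20 log10(A_{i+1}/A_i)|
    amps_db = (profile.shimmer_db * np.sqrt(np.pi) / 2.0) \
        * rng.standard_normal(n_cycles)
    amps = 10.0 ** (amps_db / 20.0)

    # per-sample frequency from cycle lengths; amplitude indexed by the
    # accumulated phase so amp switches stay aligned with cycle boundaries
    boundaries = np.round(np.cumsum(periods) * fs).astype(int)
    counts = np.diff(np.concatenate([[0], boundaries]))
    counts = np.maximum(counts, 1)
    freq_per_cycle = 1.0 / periods
    inst_freq = np.repeat(freq_per_cycle, counts)[:n_total]
    if len(inst_freq) < n_total:  # pad defensively
        pad = n_total - len(inst_freq)
        inst_freq = np.concatenate([inst_freq, np.full(pad, f0)])
    phase = 2.0 * np.pi * np.cumsum(inst_freq) / fs
    # half-cycle shift: the 1/k harmonic sum peaks at the phase wrap, so
    # amp switches are placed mid-cycle to keep each peak within one segment
    cycle_idx = np.minimum(np.floor(phase / (2 * np.pi) + 0.5).astype(int),
                           n_cycles - 1)
    inst_amp = amps[cycle_idx]

    harm = np.zeros(n_total)
    for k in range(1, n_harmonics + 1):
        harm += (1.0 / k) * np.sin(k * phase)
    harm *= inst_amp

    p_harm = float(np.mean(harm ** 2))
    p_noise = p_harm / (10.0 ** (profile.hnr_target_db / 10.0))
    noise = np.sqrt(p_noise) * rng.standard_normal(n_total)
    samples = harm + noise
    samples = 0.7 * samples / np.max(np.abs(samples))
    clip = AudioClip(samples, fs)
    truth = {
        "f0_hz": f0,
        "jitter_pct": profile.jitter_pct,
        "shimmer_db": profile.shimmer_db,
        "hnr_target_db": profile.hnr_target_db,
    }
    return clip, truth


# ---------------------------------------------------------------------------
# Full cohort
# ---------------------------------------------------------------------------

def synth_cohort(n: int = 194, seed: int = 0,
                 control_profile: ClassEffectProfile = CONTROL_PROFILE,
                 pd_profile: ClassEffectProfile = PD_PROFILE,
                 train_count: int | None = None,
                 test_count: int | None = None,
                 voice_duration_s: float = 10.0,
                 gait_duration_s: float = 30.0,
                 out_dir=None) -> tuple[CohortTable, dict, pd.DataFrame]:
    """Generate a complete balanced cohort with all four modalities.

    Returns the cohort table (with its stratified train/test split), a
    map participant_id -> modality objects, and a ground-truth parameter
    table.  If ``out_dir`` is given the raw files (CSV traces, JSON tap
    events, WAV audio) and manifest are also written in the layouts the
    readers accept.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if pd_profile.label == control_profile.label:
        raise ValueError("profiles must carry distinct labels")
    rng = np.random.default_rng(seed)
    records = synth_demographics(n, seed=int(rng.integers(2 ** 31)))
    if train_count is None:
        train_count = int(round(n * 164 / 194))
    if test_count is None:
        test_count = n - train_count
    data: dict[str, dict] = {}
    truths = []
    for rec in records:
        profile = pd_profile if rec.label == "PD" else control_profile
        sub = int(rng.integers(2 ** 31))
        gait, g_truth = synth_gait(profile, duration_s=gait_duration_s,
                                   seed=sub)
        taps, tap_accel, t_truth = synth_taps(profile, seed=sub + 1)
        voice, v_truth = synth_voice(profile, gender=rec.gender,
                                     duration_s=voice_duration_s,
                                     seed=sub + 2)
        data[rec.participant_id] = {
            "gait": gait, "taps": taps, "tap_accel": tap_accel,
            "voice": voice,
        }
        truths.append({"participant_id": rec.participant_id,
                       "label": rec.label, **g_truth, **t_truth, **v_truth})
    cohort = assemble_cohort(records, train_count=train_count,
                             test_count=test_count, seed=seed)
    truth_df = pd.DataFrame(truths).set_index("participant_id")
    if out_dir is not None:
        _write_cohort(out_dir, cohort, data, truth_df)
    return cohort, data, truth_df


def _write_cohort(out_dir, cohort: CohortTable, data: dict,
                  truth_df: pd.DataFrame) -> None:
    import json
    from pathlib import Path

    from .io import write_wav

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in cohort.records:
        pdir = out / rec.participant_id
        pdir.mkdir(exist_ok=True)
        d = data[rec.participant_id]
        for name, trace in (("gait", d["gait"]), ("tap_accel",
                                                  d["tap_accel"])):
            pd.DataFrame({"t": trace.timestamps, "x": trace.x,
                          "y": trace.y, "z": trace.z}).to_csv(
                pdir / f"{name}.csv", index=False)
        with open(pdir / "taps.json", "w") as fh:
            json.dump([{"time": float(t), "button": b}
                       for t, b in zip(d["taps"].times, d["taps"].buttons)],
                      fh)
        write_wav(pdir / "voice.wav", d["voice"])
    cohort.manifest().to_csv(out / "manifest.csv", index=False)
    truth_df.to_csv(out / "ground_truth.csv")
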
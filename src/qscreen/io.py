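"""Reading and validation of the four smartphone modality formats.

Each participant in an mPower-style cohort contributes tri-axial
accelerometer traces (gait and tapping phases), a timestamped stream of
left/right button tap events, a sustained-phonation audio clip, and a
demographics row.  This module parses those files into validated domain
objects, selects one trial per participant per activity, and assembles a
complete-case cohort with a stratified train/test split.
"""

from __future__ import annotations

import io as _io
import json
import logging
import wave
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_SPLIT_SEED = 20250404


class ParseError(ValueError):
    """Malformed input stream; message names the offending line."""


class InsufficientDataError(ValueError):
    """Too few samples to form a valid trace."""


class CohortError(ValueError):
    """Cohort cannot be assembled (e.g. a class has < 2 participants)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class AccelerometerTrace:
    """Uniformly sampled tri-axial acceleration time series.

    Timestamps are shifted so the first sample is at t=0; only relative
    timing matters downstream.  The acceleration unit (g or m/s^2) is
    recorded but never converted: every extracted feature is
    scale-covariant and later standardized.
    """

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    sample_rate_hz: float
    source_activity: str = "gait"
    unit: str = "g"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.timestamps)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise ValueError("axis series lengths differ")
        if n < 2:
            raise InsufficientDataError("trace needs at least 2 samples")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if np.diff(self.timestamps).min() < 0:
            raise ValueError("timestamps must be non-decreasing")
        for arr in (self.x, self.y, self.z):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite acceleration value")

    def __len__(self) -> int:
        return len(self.timestamps)


@dataclass
class TapEventSeries:
    """Timestamped left/right button presses within a fixed test window."""

    times: np.ndarray
    buttons: list[str]
    window_seconds: float = 20.0
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.buttons):
            raise ValueError("times/buttons length mismatch")
        for b in self.buttons:
            if b not in ("left", "right"):
                raise ValueError(f"unknown button label: {b!r}")
        if len(self.times) > 1 and np.diff(self.times).min() < 0:
            raise ValueError("tap times must be sorted")

    @property
    def is_empty(self) -> bool:
        return len(self.times) == 0

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class AudioClip:
    """Mono audio with amplitudes normalized to [-1, 1]."""

    samples: np.ndarray
    sample_rate_hz: int
    duration_flag: bool = False  # True if outside the expected task bounds

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("AudioClip must be mono")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.sample_rate_hz


@dataclass
class ParticipantRecord:
    """One participant: demographics, diagnosis label and trial references."""

    participant_id: str
    age: float
    gender: str
    smoker: bool
    label: str | None = None  # "PD" or "control"
    trial_refs: dict = field(default_factory=dict)  # activity -> list of refs
    split: str | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.label is not None and self.label not in ("PD", "control"):
            raise ValueError(f"unknown label {self.label!r}")


ACTIVITIES = ("gait", "tapping", "voice")


@dataclass
class CohortTable:
    """Complete-case cohort: one selected trial per activity per participant."""

    records: list[ParticipantRecord]

    def __post_init__(self) -> None:
        ids = [r.participant_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("participant_ids not unique")
        for r in self.records:
            for act in ACTIVITIES:
                if len(r.trial_refs.get(act, [])) != 1:
                    raise ValueError(
                        f"{r.participant_id} lacks a single {act} trial"
                    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def train(self) -> list[ParticipantRecord]:
        return [r for r in self.records if r.split == "train"]

    @property
    def test(self) -> list[ParticipantRecord]:
        return [r for r in self.records if r.split == "test"]

    def manifest(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "participant_id": r.participant_id,
                    "age": r.age,
                    "gender": r.gender,
                    "smoker": r.smoker,
                    "label": r.label,
                    "split": r.split,
                    **{f"{a}_ref": r.trial_refs[a][0] for a in ACTIVITIES},
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _lower_median(values: np.ndarray) -> float:
    """Median as an order statistic: for even counts take the lower middle.

    Favors the denser native sampling interval so no information is lost
    when the device's timestamp jitter is asymmetric.
    """
    s = np.sort(values)
    return float(s[(len(s) - 1) // 2])


def _resample_uniform(t, x, y, z):
    """Linear interpolation onto a uniform grid at the lower-median rate."""
    t = t - t[0]
    dts = np.diff(t)
    dts = dts[dts > 0]
    if len(dts) == 0:
        raise InsufficientDataError("all timestamps identical")
    dt = _lower_median(dts)
    n = int(round(t[-1] / dt)) + 1
    grid = np.arange(n) * dt
    out = tuple(np.interp(grid, t, a) for a in (x, y, z))
    return grid, out, 1.0 / dt


def read_accel_trace(stream, dialect: str = "csv",
                     source_activity: str = "gait",
                     unit: str = "g") -> AccelerometerTrace:
    """Parse an accelerometer file (CSV ``t,x,y,z`` or JSON records).

    Irregular timestamps are resampled to a uniform grid by linear
    interpolation at the (lower-)median native rate; the time origin is
    shifted to zero.
    """
    if isinstance(stream, (str, bytes)):
        stream = _io.StringIO(
            stream.decode() if isinstance(stream, bytes) else stream
        )
    if dialect == "json_records":
        try:
            records = json.load(stream)
        except json.JSONDecodeError as e:
            raise ParseError(f"malformed JSON: {e}") from e
        try:
            t = np.array([float(r["timestamp"]) for r in records])
            x = np.array([float(r["x"]) for r in records])
            y = np.array([float(r["y"]) for r in records])
            z = np.array([float(r["z"]) for r in records])
        except (KeyError, TypeError, ValueError) as e:
            raise ParseError(f"malformed JSON record: {e}") from e
    elif dialect == "csv":
        t_l, x_l, y_l, z_l = [], [], [], []
        for lineno, line in enumerate(stream, start=1):
            line = line.strip()
            if not line:
                continue
            if lineno == 1 and any(c.isalpha() for c in line.split(",")[0]):
                continue  # header
            parts = line.split(",")
            if len(parts) != 4:
                raise ParseError(f"line {lineno}: expected 4 fields")
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                raise ParseError(f"line {lineno}: non-numeric field") from None
            if not all(np.isfinite(vals)):
                raise ParseError(f"line {lineno}: non-finite value")
            t_l.append(vals[0]); x_l.append(vals[1])
            y_l.append(vals[2]); z_l.append(vals[3])
        t, x, y, z = map(np.array, (t_l, x_l, y_l, z_l))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if len(t) < 2:
        raise InsufficientDataError("accelerometer trace needs >= 2 samples")
    order = np.argsort(t, kind="stable")
    t, x, y, z = t[order], x[order], y[order], z[order]
    grid, (xi, yi, zi), fs = _resample_uniform(t, x, y, z)
    return AccelerometerTrace(grid, xi, yi, zi, sample_rate_hz=fs,
                              source_activity=source_activity, unit=unit)


def read_tap_events(stream, window_seconds: float = 20.0) -> TapEventSeries:
    """Parse tap events (JSON records or CSV ``time,button``).

    Events after the test window are dropped with a logged count; events
    arrive in any order and are sorted.
    """
    if isinstance(stream, (str, bytes)):
        stream = _io.StringIO(
            stream.decode() if isinstance(stream, bytes) else stream
        )
    text = stream.read()
    stripped = text.lstrip()
    events: list[tuple[float, str]] = []
    if stripped.startswith("["):
        for r in json.loads(text):
            events.append((float(r["time"]), str(r["button"]).lower()))
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if parts[1].strip().lower() == "button":
                continue
            events.append((float(parts[0]), parts[1].strip().lower()))
    for _, b in events:
        if b not in ("left", "right"):
            raise ValueError(f"unknown button label: {b!r}")
    events.sort(key=lambda e: e[0])
    kept = [(t, b) for t, b in events if 0.0 <= t <= window_seconds]
    n_dropped = len(events) - len(kept)
    if n_dropped:
        logger.info("read_tap_events: dropped %d events outside window",
                    n_dropped)
    return TapEventSeries(
        np.array([t for t, _ in kept]),
        [b for _, b in kept],
        window_seconds=window_seconds,
        n_dropped=n_dropped,
    )


def read_audio(stream, duration_bounds: tuple[float, float] = (8.0, 12.0)
               ) -> AudioClip:
    """Read a PCM WAV file into a mono, [-1, 1]-normalized clip.

    Stereo channels are averaged; integer PCM is scaled by 2^(bits-1).
    A clip outside the expected task duration is flagged, not rejected.
    """
    if isinstance(stream, bytes):
        stream = _io.BytesIO(stream)
    close = False
    if isinstance(stream, str):
        stream = open(stream, "rb")
        close = True
    try:
        try:
            wf = wave.open(stream, "rb")
        except (wave.Error, EOFError) as e:
            raise ValueError(f"not a PCM WAV stream: {e}") from e
        with wf:
            n_ch = wf.getnchannels()
            width = wf.getsampwidth()
            fs = wf.getframerate()
            raw = wf.readframes(wf.getnframes())
    finally:
        if close:
            stream.close()
    if width == 2:
        data = np.frombuffer(raw, dtype="<i2").astype(float) / 32768.0
    elif width == 3:
        b = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 3)
        vals = (b[:, 0].astype(np.int32)
                | (b[:, 1].astype(np.int32) << 8)
                | (b[:, 2].astype(np.int32) << 16))
        vals = np.where(vals >= 2 ** 23, vals - 2 ** 24, vals)
        data = vals.astype(float) / 2.0 ** 23
    elif width == 1:
        data = (np.frombuffer(raw, dtype=np.uint8).astype(float) - 128) / 128.0
    else:
        raise ValueError(f"unsupported PCM width {width * 8} bits")
    if n_ch > 1:
        data = data.reshape(-1, n_ch).mean(axis=1)
    clip = AudioClip(data, fs)
    lo, hi = duration_bounds
    clip.duration_flag = not (lo <= clip.duration_s <= hi)
    return clip


def write_wav(path, clip: AudioClip) -> None:
    """Write a clip back out as 16-bit PCM WAV."""
    pcm = np.clip(np.round(clip.samples * 32768.0), -32768, 32767).astype("<i2")
    with wave.open(str(path), "wb") as wf:
        wf.setnchannels(1)
        wf.setsampwidth(2)
        wf.setframerate(clip.sample_rate_hz)
        wf.writeframes(pcm.tobytes())


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def select_single_trial(records: list[ParticipantRecord],
                        seed: int) -> list[ParticipantRecord]:
    """Keep exactly one uniformly random trial per participant per activity.

    Keeping one trial prevents participants with many repeat sessions from
    dominating the training set.  Deterministic under a fixed seed and
    independent of input ordering (records are processed sorted by id).
    """
    rng = np.random.default_rng(seed)
    out = []
    for rec in sorted(records, key=lambda r: r.participant_id):
        refs = {}
        for act in sorted(rec.trial_refs):
            trials = rec.trial_refs[act]
            if len(trials) == 0:
                refs[act] = []
            else:
                refs[act] = [trials[int(rng.integers(len(trials)))]]
        out.append(ParticipantRecord(rec.participant_id, rec.age, rec.gender,
                                     rec.smoker, rec.label, refs))
    return out


def assemble_cohort(records: list[ParticipantRecord],
                    train_count: int | None = None,
                    test_count: int | None = None,
                    train_fraction: float | None = None,
                    seed: int = DEFAULT_SPLIT_SEED) -> CohortTable:
    """Filter to complete cases and split stratified by diagnosis label.

    Participants missing any of the gait/tapping/voice activities are
    excluded (logged).  The split is stratified so each class's train/test
    proportions match the overall split to within one participant.
    """
    complete = []
    for rec in records:
        missing = [a for a in ACTIVITIES if len(rec.trial_refs.get(a, [])) < 1]
        if missing:
            logger.info("excluding %s: missing %s",
                        rec.participant_id, ",".join(missing))
            continue
        if rec.label is None:
            logger.info("excluding %s: no diagnosis label", rec.participant_id)
            continue
        complete.append(rec)

    n = len(complete)
    for lab in ("PD", "control"):
        if sum(r.label == lab for r in complete) < 2:
            raise CohortError(f"fewer than 2 participants with label {lab}")
    if train_count is None:
        if train_fraction is None:
            train_fraction = 164 / 194
        train_count = int(round(n * train_fraction))
    if test_count is None:
        test_count = n - train_count
    if train_count + test_count > n:
        raise CohortError(f"split {train_count}+{test_count} exceeds n={n}")

    # Stratified assignment: allocate test slots per class by largest
    # remainder so class proportions are preserved to within one participant.
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[ParticipantRecord]] = {}
    for rec in sorted(complete, key=lambda r: r.participant_id):
        by_class.setdefault(rec.label, []).append(rec)
    test_frac = test_count / (train_count + test_count)
    quotas, remainders = {}, {}
    for lab, group in sorted(by_class.items()):
        exact = len(group) * test_frac
        quotas[lab] = int(np.floor(exact))
        remainders[lab] = exact - quotas[lab]
    short = test_count - sum(quotas.values())
    for lab in sorted(remainders, key=remainders.get, reverse=True)[:short]:
        quotas[lab] += 1

    for lab, group in sorted(by_class.items()):
        idx = rng.permutation(len(group))
        test_idx = set(idx[: quotas[lab]].tolist())
        for i, rec in enumerate(group):
            rec.split = "test" if i in test_idx else "train"
    logger.info("cohort: %d train / %d test of %d complete cases",
                sum(r.split == "train" for r in complete),
                sum(r.split == "test" for r in complete), n)
    return CohortTable(complete)
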
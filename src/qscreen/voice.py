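"""Sustained-phonation acoustic feature extraction.

Works on 10-second "ahh" recordings.  Produces pitch and volume
statistics, frame-level signal descriptors (zero-crossing rate, RMS,
spectral centroid/bandwidth/rolloff), perturbation measures (shimmer in
dB), periodicity measures (autocorrelation HNR, smoothed cepstral peak
prominence), breathiness components (glottal-to-noise excitation ratio,
first-to-second harmonic difference, high-frequency noise fraction above
6 kHz, a two-band Welch PSD level difference) combined into a
configurable Acoustic Breathiness Index, and PCA-reduced MFCC features.

A breathy, unstable voice — reduced harmonicity, raised spectral noise,
cycle-to-cycle amplitude perturbation — is the vocal signature of
hypokinetic dysarthria that these measures quantify.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .io import AudioClip

VOICE_SCALAR_FEATURES = (
    "voice_pitch_mean_hz", "voice_pitch_std_hz",
    "voice_volume_mean", "voice_volume_std",
    "voice_zcr_mean", "voice_zcr_std",
    "voice_spectral_centroid_mean", "voice_spectral_centroid_std",
    "voice_spectral_bandwidth_mean", "voice_spectral_bandwidth_std",
    "voice_spectral_rolloff_mean", "voice_spectral_rolloff_std",
    "voice_shimmer_db", "voice_hnr_db", "voice_cpp_db", "voice_gne",
    "voice_h1_h2_db", "voice_hf_noise_6000", "voice_psd_summary",
    "voice_abi",
)
MFCC_PCA_FEATURES = tuple(f"voice_mfcc_pc{i + 1}" for i in range(10))

# Package-default ABI coefficients.  The index is an affine combination of
# the breathiness components; these defaults encode the expected
# directionality (breathier voices score higher: harmonicity measures
# enter negatively, noise measures positively) and are meant to be
# replaced by any externally calibrated coefficient set via config.
DEFAULT_ABI_COEFFICIENTS: dict[str, float] = {
    "intercept": 7.0,
    "cpp_smoothed_db": -0.25,
    "hnr_db": -0.13,
    "shimmer_db": 0.75,
    "gne_ratio": -2.0,
    "h1_h2_db": 0.05,
    "hf_noise_6000": 4.0,
    "psd_summary": -0.02,
}


@dataclass
class FrameGrid:
    """Hann-windowed overlapping analysis frames of a clip."""

    frames: np.ndarray           # (n_frames, frame_len), window applied
    raw_frames: np.ndarray       # same blocks without the window
    sample_rate_hz: int
    frame_length_s: float = 0.040
    hop_s: float = 0.010

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_len(self) -> int:
        return self.frames.shape[1]


@dataclass
class PitchTrack:
    f0_hz: np.ndarray            # per frame; NaN where unvoiced
    voiced: np.ndarray           # boolean per frame
    hop_s: float

    @property
    def any_voiced(self) -> bool:
        return bool(self.voiced.any())

    def stats(self) -> tuple[float, float]:
        """(mean, population std) of f0 over voiced frames; NaN if none."""
        if not self.any_voiced:
            return float("nan"), float("nan")
        v = self.f0_hz[self.voiced]
        return float(np.mean(v)), float(np.std(v))


def frame_signal(clip: AudioClip, frame_length_s: float = 0.040,
                 hop_s: float = 0.010) -> FrameGrid:
    """Slice the clip into Hann-windowed overlapping frames."""
    L = int(round(frame_length_s * clip.sample_rate_hz))
    H = int(round(hop_s * clip.sample_rate_hz))
    n = len(clip.samples)
    if n < L:
        raise ValueError(f"clip ({n} samples) shorter than one frame ({L})")
    n_frames = (n - L) // H + 1
    idx = np.arange(L)[None, :] + H * np.arange(n_frames)[:, None]
    raw = clip.samples[idx]
    win = np.hanning(L)
    return FrameGrid(raw * win, raw, clip.sample_rate_hz,
                     frame_length_s, hop_s)


# ---------------------------------------------------------------------------
# Pitch
# ---------------------------------------------------------------------------

def _frame_autocorr(raw_frames: np.ndarray) -> np.ndarray:
    """Unbiased autocorrelation of each (mean-removed) frame via FFT.

    The raw FFT estimate carries a (L - k)/L taper that would bias pitch
    peaks and HNR low at large lags; dividing it out makes r(lag)/r(0)
    approach the true normalized autocorrelation for lags well below L.
    """
    x = raw_frames - raw_frames.mean(axis=1, keepdims=True)
    L = x.shape[1]
    nfft = int(2 ** np.ceil(np.log2(2 * L)))
    X = np.fft.rfft(x, n=nfft, axis=1)
    r = np.fft.irfft(np.abs(X) ** 2, n=nfft, axis=1)[:, :L]
    taper = (L - np.arange(L)) / L
    return r / taper


def _parabolic_peak(y_m1, y_0, y_p1):
    """Vertex offset/value of the parabola through three equally spaced points."""
    denom = y_m1 - 2 * y_0 + y_p1
    delta = np.where(np.abs(denom) > 1e-30,
                     0.5 * (y_m1 - y_p1) / np.where(denom == 0, 1, denom), 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    value = y_0 - 0.25 * (y_m1 - y_p1) * delta
    return delta, value


def pitch_track(grid: FrameGrid, f_min: float = 50.0, f_max: float = 500.0,
                voicing_threshold: float = 0.3,
                octave_cost: float = 0.1) -> PitchTrack:
    """Autocorrelation pitch with parabolic lag interpolation.

    A frame is voiced when its normalized autocorrelation peak inside the
    [f_min, f_max] lag range reaches ``voicing_threshold``.  Candidate
    lags are scored with a small log-lag penalty (``octave_cost`` per
    octave) because a perfectly periodic signal peaks equally at every
    multiple of its period; without the penalty the tracker can lock onto
    subharmonics.
    """
    fs = grid.sample_rate_hz
    r = _frame_autocorr(grid.raw_frames)
    r0 = r[:, 0].copy()
    silent = r0 < 1e-14
    r0[silent] = 1.0
    rn = r / r0[:, None]
    lag_min = max(2, int(np.floor(fs / f_max)))
    lag_max = min(r.shape[1] - 2, int(np.ceil(fs / f_min)))
    if lag_max <= lag_min:
        raise ValueError("frame too short for the pitch search range")
    lags = np.arange(lag_min, lag_max + 1)
    penalty = octave_cost * np.log2(lags / lag_min)
    seg = rn[:, lag_min:lag_max + 1] - penalty[None, :]
    best = np.argmax(seg, axis=1) + lag_min
    rows = np.arange(r.shape[0])
    delta, peak_val = _parabolic_peak(rn[rows, best - 1], rn[rows, best],
                                      rn[rows, best + 1])
    lag = best + delta
    f0 = fs / lag
    voiced = (peak_val >= voicing_threshold) & ~silent \
        & (f0 >= f_min) & (f0 <= f_max)
    f0 = np.where(voiced, f0, np.nan)
    return PitchTrack(f0, voiced, grid.hop_s)


# ---------------------------------------------------------------------------
# Frame-level descriptors
# ---------------------------------------------------------------------------

def frame_descriptors(grid: FrameGrid,
                      rolloff_fraction: float = 0.85) -> dict[str, float]:
    """Means/stds of ZCR, RMS volume, spectral centroid/bandwidth/rolloff.

    ZCR is reported as crossings per second; spectral descriptors use the
    frame magnitude spectrum with the DC bin excluded; rolloff is the
    lowest frequency below which ``rolloff_fraction`` of spectral energy
    (A^2) lies.  Silent frames contribute zeros.
    """
    fs = grid.sample_rate_hz
    raw = grid.raw_frames
    n_frames, L = raw.shape

    crossings = np.sum(np.abs(np.diff(np.signbit(raw), axis=1)), axis=1)
    zcr = crossings * fs / L  # per second
    rms = np.sqrt(np.mean(grid.frames ** 2, axis=1))

    amp = np.abs(np.fft.rfft(grid.frames, axis=1))[:, 1:]
    freqs = np.fft.rfftfreq(L, d=1.0 / fs)[1:]
    total = amp.sum(axis=1)
    ok = total > 1e-14
    safe_total = np.where(ok, total, 1.0)

    centroid = np.where(ok, (amp * freqs).sum(axis=1) / safe_total, 0.0)
    bw = np.where(
        ok,
        np.sqrt(((freqs[None, :] - centroid[:, None]) ** 2 * amp
                 ).sum(axis=1) / safe_total),
        0.0,
    )
    energy = amp ** 2
    e_total = energy.sum(axis=1)
    e_ok = e_total > 1e-28
    cum = np.cumsum(energy, axis=1)
    thresh = rolloff_fraction * e_total[:, None]
    roll_idx = np.argmax(cum >= thresh, axis=1)
    rolloff = np.where(e_ok, freqs[roll_idx], 0.0)

    out = {}
    for name, arr in (("zcr", zcr), ("volume", rms),
                      ("spectral_centroid", centroid),
                      ("spectral_bandwidth", bw),
                      ("spectral_rolloff", rolloff)):
        out[f"{name}_mean"] = float(np.mean(arr))
        out[f"{name}_std"] = float(np.std(arr))
    return out


# ---------------------------------------------------------------------------
# Perturbation and periodicity measures
# ---------------------------------------------------------------------------

def _cycle_peaks(clip: AudioClip, track: PitchTrack) -> np.ndarray:
    """Peak |amplitude| of each pitch cycle.

    Cycle peaks are located as local maxima of |x| at least ~0.7 pitch
    periods apart (anchoring on the waveform itself avoids the phase
    drift a fixed-period grid walk accumulates over a long clip)."""
    if not track.any_voiced:
        return np.array([])
    f0 = float(np.nanmedian(track.f0_hz))
    period = clip.sample_rate_hz / f0
    x = np.abs(clip.samples)
    idx, _ = sps.find_peaks(x, distance=max(2, int(0.7 * period)),
                            height=0.05 * x.max())
    return x[idx]


def shimmer_db(clip: AudioClip, track: PitchTrack) -> float:
    """Mean |20 log10(A_{i+1}/A_i)| over consecutive cycle peak amplitudes."""
    peaks = _cycle_peaks(clip, track)
    peaks = peaks[peaks > 1e-12]
    if len(peaks) < 3:
        return float("nan")
    ratios = peaks[1:] / peaks[:-1]
    return float(np.mean(np.abs(20.0 * np.log10(ratios))))


def hnr_db(grid: FrameGrid, track: PitchTrack, cap_db: float = 40.0) -> float:
    """Autocorrelation harmonics-to-noise ratio in dB, averaged over voiced
    frames: HNR = 10 log10(r / (1 - r)) at the (interpolated) pitch lag."""
    if not track.any_voiced:
        return float("nan")
    fs = grid.sample_rate_hz
    r = _frame_autocorr(grid.raw_frames)
    r0 = r[:, 0].copy()
    r0[r0 < 1e-14] = 1.0
    rn = r / r0[:, None]
    vals = []
    for i in np.flatnonzero(track.voiced):
        lag = fs / track.f0_hz[i]
        k = int(round(lag))
        if k < 1 or k > rn.shape[1] - 2:
            continue
        # parabolic vertex: the true peak generally sits at a fractional
        # lag, and sampling the integer lag alone biases the ratio low
        # for sharply peaked (very harmonic) autocorrelations
        _, peak = _parabolic_peak(rn[i, k - 1], rn[i, k], rn[i, k + 1])
        peak = min(max(float(peak), 1e-6), 1.0 - 1e-6)
        vals.append(10.0 * np.log10(peak / (1.0 - peak)))
    if not vals:
        return float("nan")
    return float(min(np.mean(vals), cap_db))


def cpp_smoothed_db(clip: AudioClip, f_min: float = 50.0,
                    f_max: float = 500.0, frame_length_s: float = 0.040,
                    hop_s: float = 0.010) -> float:
    """Smoothed cepstral peak prominence (CPPs) in dB.

    Frame log-magnitude spectra are turned into real cepstra, smoothed
    across time (7 frames) and quefrency (11 bins), and the prominence of
    the peak in the pitch-equivalent quefrency band over the linear
    regression trend (fit from 1 ms up) is averaged over frames.  Being a
    log-domain measure it is invariant to amplitude scaling.
    """
    grid = frame_signal(clip, frame_length_s, hop_s)
    fs = grid.sample_rate_hz
    L = grid.frame_len
    nfft = int(2 ** np.ceil(np.log2(L)))
    spec = np.abs(np.fft.rfft(grid.frames, n=nfft, axis=1))
    log_spec = 20.0 * np.log10(np.maximum(spec, 1e-12))
    # factor 2: the k-th irfft coefficient times 2 is the amplitude of the
    # cosine ripple at that quefrency in the dB spectrum, so the peak reads
    # as the comb depth in dB
    cep = 2.0 * np.fft.irfft(log_spec, n=nfft, axis=1)[:, : nfft // 2]

    def smooth(a, w, axis):
        kernel = np.ones(w) / w
        return np.apply_along_axis(
            lambda v: np.convolve(v, kernel, mode="same"), axis, a)

    if cep.shape[0] >= 7:
        cep = smooth(cep, 7, 0)
    cep = smooth(cep, 5, 1)

    quef = np.arange(nfft // 2) / fs
    band = (quef >= 1.0 / f_max) & (quef <= 1.0 / f_min)
    fit_region = quef >= 0.001
    q_fit = quef[fit_region]
    vals = []
    for row in cep:
        slope, intercept = np.polyfit(q_fit, row[fit_region], 1)
        seg = row[band]
        k = int(np.argmax(seg))
        q_peak = quef[band][k]
        trend = slope * q_peak + intercept
        vals.append(seg[k] - trend)
    return float(np.mean(vals))


def _lpc_residual(x: np.ndarray, order: int = 13) -> np.ndarray:
    """Inverse-filter the signal with LPC coefficients (autocorrelation
    method, Toeplitz solve) to flatten the vocal-tract envelope.

    For voiced speech the residual approaches a broadband glottal pulse
    train, which is what the GNE band-envelope construction assumes.
    """
    from scipy.linalg import solve_toeplitz

    x = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * len(x))))
    X = np.fft.rfft(x, n=nfft)
    r = np.fft.irfft(np.abs(X) ** 2, n=nfft)[: order + 1]
    if r[0] <= 0:
        return x
    r = r + 1e-9 * r[0] * (np.arange(order + 1) == 0)  # regularize
    a = solve_toeplitz((r[:order], r[:order]), r[1:order + 1])
    return sps.lfilter(np.concatenate([[1.0], -a]), [1.0], x)


def gne_ratio(clip: AudioClip, band_width_hz: float = 3000.0,
              band_step_hz: float = 500.0,
              segment_s: float = 0.1) -> float:
    """Glottal-to-noise excitation ratio in [0, 1].

    The clip is resampled to 10 kHz and inverse-filtered (LPC) so voiced
    excitation appears as a broadband pulse train; the residual is split
    into bands of ``band_width_hz`` stepped by ``band_step_hz``, and the
    maximum cross-correlation between Hilbert envelopes of bands whose
    centres differ by at least half the bandwidth is averaged over short
    segments.  Pulsed (glottal) excitation drives all band envelopes in
    unison, giving values near 1; turbulent noise decorrelates them.
    """
    fs_t = 10000
    x = clip.samples
    if clip.sample_rate_hz != fs_t:
        g = np.gcd(int(clip.sample_rate_hz), fs_t)
        x = sps.resample_poly(x, fs_t // g, int(clip.sample_rate_hz) // g)
    x = _lpc_residual(x)
    nyq = fs_t / 2.0
    starts = np.arange(0.0, nyq - band_width_hz + 1e-9, band_step_hz)
    X = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs_t)
    envelopes, centers = [], []
    for s in starts:
        mask = (freqs >= s) & (freqs < s + band_width_hz)
        Xb = np.where(mask, X, 0.0)
        band = np.fft.irfft(Xb, n=len(x))
        envelopes.append(np.abs(sps.hilbert(band)))
        centers.append(s + band_width_hz / 2.0)
    envelopes = np.array(envelopes)
    centers = np.array(centers)
    half_bw = band_width_hz / 2.0

    seg_len = int(segment_s * fs_t)
    n_seg = max(1, len(x) // seg_len)
    vals = []
    for si in range(n_seg):
        seg = envelopes[:, si * seg_len:(si + 1) * seg_len]
        seg = seg - seg.mean(axis=1, keepdims=True)
        norms = np.sqrt((seg ** 2).sum(axis=1))
        norms[norms < 1e-14] = 1.0
        segn = seg / norms[:, None]
        corr = segn @ segn.T
        best = 0.0
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if centers[j] - centers[i] >= half_bw:
                    best = max(best, corr[i, j])
        vals.append(best)
    return float(np.clip(np.mean(vals), 0.0, 1.0))


def _interp_harmonic_level(freqs, amp, f_target, tol_hz):
    """Parabolic-interpolated spectral peak level (dB) near f_target."""
    mask = (freqs >= f_target - tol_hz) & (freqs <= f_target + tol_hz)
    if not mask.any():
        return float("nan")
    idx = np.flatnonzero(mask)
    k = idx[np.argmax(amp[idx])]
    if 1 <= k < len(amp) - 1:
        _, peak = _parabolic_peak(amp[k - 1], amp[k], amp[k + 1])
        peak = max(float(peak), 1e-12)
    else:
        peak = max(float(amp[k]), 1e-12)
    return 20.0 * np.log10(peak)


def spectral_noise_measures(clip: AudioClip, track: PitchTrack
                            ) -> dict[str, float]:
    """First-to-second harmonic difference, HF noise fraction, PSD summary.

    h1_h2_db: level difference between the first and second harmonic
    (parabolic-interpolated spectral peaks at f0 and 2 f0).
    hf_noise_6000: spectral energy above 6 kHz / total (missing when the
    sample rate cannot observe 6 kHz).
    psd_summary: mean Welch PSD level in 0-1 kHz minus 1-5 kHz, in dB —
    a crude low/high spectral balance used as a breathiness input.
    """
    fs = clip.sample_rate_hz
    out: dict[str, float] = {}

    if track.any_voiced:
        f0 = float(np.nanmedian(track.f0_hz))
        amp = np.abs(np.fft.rfft(clip.samples))
        freqs = np.fft.rfftfreq(len(clip.samples), d=1.0 / fs)
        h1 = _interp_harmonic_level(freqs, amp, f0, 0.2 * f0)
        h2 = _interp_harmonic_level(freqs, amp, 2 * f0, 0.2 * f0)
        out["h1_h2_db"] = h1 - h2
    else:
        out["h1_h2_db"] = float("nan")

    power = np.abs(np.fft.rfft(clip.samples)) ** 2
    freqs = np.fft.rfftfreq(len(clip.samples), d=1.0 / fs)
    if fs < 12000:
        out["hf_noise_6000"] = float("nan")
    else:
        total = power.sum()
        out["hf_noise_6000"] = (
            float(power[freqs >= 6000.0].sum() / total) if total > 0 else 0.0
        )

    nper = min(len(clip.samples), 2048)
    f_w, pxx = sps.welch(clip.samples, fs=fs, nperseg=nper)
    lo = pxx[(f_w > 0) & (f_w <= 1000.0)]
    hi = pxx[(f_w > 1000.0) & (f_w <= 5000.0)]
    if len(lo) and len(hi) and lo.mean() > 0 and hi.mean() > 0:
        out["psd_summary"] = float(10.0 * np.log10(lo.mean() / hi.mean()))
    else:
        out["psd_summary"] = float("nan")
    return out


def abi_score(components: dict[str, float],
              coefficients: dict[str, float] | None = None) -> float:
    """Affine Acoustic Breathiness Index from its component measures.

    ``ABI = intercept + sum_k beta_k * component_k`` with the coefficient
    set taken from config (see DEFAULT_ABI_COEFFICIENTS).  Missing
    components yield a missing index (NaN).
    """
    coeff = dict(DEFAULT_ABI_COEFFICIENTS if coefficients is None
                 else coefficients)
    total = coeff.pop("intercept", 0.0)
    for name, beta in coeff.items():
        val = components.get(name, float("nan"))
        if val is None or not np.isfinite(val):
            return float("nan")
        total += beta * val
    return float(total)


# ---------------------------------------------------------------------------
# MFCC + PCA
# ---------------------------------------------------------------------------

def _hz_to_mel(f):
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=float) / 700.0)


def _mel_to_hz(m):
    return 700.0 * (10.0 ** (np.asarray(m, dtype=float) / 2595.0) - 1.0)


def _mel_filterbank(n_filters: int, nfft: int, fs: int,
                    f_lo: float = 0.0, f_hi: float | None = None) -> np.ndarray:
    if f_hi is None:
        f_hi = fs / 2.0
    mels = np.linspace(_hz_to_mel(f_lo), _hz_to_mel(f_hi), n_filters + 2)
    hz = _mel_to_hz(mels)
    bins = np.floor((nfft + 1) * hz / fs).astype(int)
    fb = np.zeros((n_filters, nfft // 2 + 1))
    for i in range(n_filters):
        a, b, c = bins[i], bins[i + 1], bins[i + 2]
        if b > a:
            fb[i, a:b] = (np.arange(a, b) - a) / (b - a)
        if c > b:
            fb[i, b:c] = (c - np.arange(b, c)) / (c - b)
    return fb


def mfcc_matrix(clip: AudioClip, n_coeff: int = 13, n_filters: int = 26,
                frame_length_s: float = 0.040, hop_s: float = 0.010
                ) -> np.ndarray:
    """Per-frame MFCCs: mel filterbank log energies followed by a DCT-II."""
    from scipy.fftpack import dct

    grid = frame_signal(clip, frame_length_s, hop_s)
    L = grid.frame_len
    nfft = int(2 ** np.ceil(np.log2(L)))
    power = np.abs(np.fft.rfft(grid.frames, n=nfft, axis=1)) ** 2
    fb = _mel_filterbank(n_filters, nfft, grid.sample_rate_hz)
    energies = power @ fb.T
    log_e = np.log(np.maximum(energies, 1e-12))
    return dct(log_e, type=2, axis=1, norm="ortho")[:, :n_coeff]


def mfcc_summary(clip: AudioClip, **kw) -> np.ndarray:
    """26-vector of per-coefficient means and stds of the frame MFCCs."""
    m = mfcc_matrix(clip, **kw)
    return np.concatenate([m.mean(axis=0), m.std(axis=0)])


@dataclass
class MfccPca:
    """PCA projection of MFCC summary vectors, fitted on training rows only."""

    mean_: np.ndarray = field(default=None)  # type: ignore[assignment]
    components_: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_components: int = 10
    n_effective: int = 10

    def fit(self, train_matrix: np.ndarray) -> "MfccPca":
        from sklearn.decomposition import PCA

        n_avail = min(self.n_components, *train_matrix.shape)
        pca = PCA(n_components=n_avail, svd_solver="full")
        pca.fit(train_matrix)
        nonzero = int(np.sum(pca.explained_variance_ > 1e-12))
        self.n_effective = nonzero
        self.mean_ = pca.mean_
        comps = pca.components_[:nonzero]
        if nonzero < self.n_components:
            pad = np.zeros((self.n_components - nonzero, train_matrix.shape[1]))
            comps = np.vstack([comps, pad])
            import warnings
            warnings.warn(
                f"MFCC PCA rank {nonzero} < {self.n_components}; zero-padding",
                stacklevel=2,
            )
        self.components_ = comps
        return self

    def transform(self, matrix: np.ndarray) -> np.ndarray:
        return (matrix - self.mean_) @ self.components_.T


# ---------------------------------------------------------------------------
# Per-clip block
# ---------------------------------------------------------------------------

def voice_feature_block(clip: AudioClip,
                        abi_coefficients: dict[str, float] | None = None
                        ) -> dict[str, float]:
    """The 20 scalar voice features (MFCC-PCA columns are cohort-level)."""
    grid = frame_signal(clip)
    track = pitch_track(grid)
    p_mean, p_std = track.stats()
    desc = frame_descriptors(grid)
    shim = shimmer_db(clip, track)
    hnr = hnr_db(grid, track)
    cpp = cpp_smoothed_db(clip)
    gne = gne_ratio(clip)
    noise = spectral_noise_measures(clip, track)
    components = {
        "cpp_smoothed_db": cpp,
        "hnr_db": hnr,
        "shimmer_db": shim,
        "gne_ratio": gne,
        "h1_h2_db": noise["h1_h2_db"],
        "hf_noise_6000": noise["hf_noise_6000"],
        "psd_summary": noise["psd_summary"],
    }
    abi = abi_score(components, abi_coefficients)
    out = {
        "voice_pitch_mean_hz": p_mean,
        "voice_pitch_std_hz": p_std,
        "voice_volume_mean": desc["volume_mean"],
        "voice_volume_std": desc["volume_std"],
        "voice_zcr_mean": desc["zcr_mean"],
        "voice_zcr_std": desc["zcr_std"],
        "voice_spectral_centroid_mean": desc["spectral_centroid_mean"],
        "voice_spectral_centroid_std": desc["spectral_centroid_std"],
        "voice_spectral_bandwidth_mean": desc["spectral_bandwidth_mean"],
        "voice_spectral_bandwidth_std": desc["spectral_bandwidth_std"],
        "voice_spectral_rolloff_mean": desc["spectral_rolloff_mean"],
        "voice_spectral_rolloff_std": desc["spectral_rolloff_std"],
        "voice_shimmer_db": shim,
        "voice_hnr_db": hnr,
        "voice_cpp_db": cpp,
        "voice_gne": gne,
        "voice_h1_h2_db": noise["h1_h2_db"],
        "voice_hf_noise_6000": noise["hf_noise_6000"],
        "voice_psd_summary": noise["psd_summary"],
        "voice_abi": abi,
    }
    assert set(out) == set(VOICE_SCALAR_FEATURES)
    return out
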
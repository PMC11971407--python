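# Methods

This note records the modelling and numerical decisions behind `qscreen`:
what each stage computes, which constants matter and why they hold their
defaults, what the synthetic cohort does and does not emulate, and the
known limitations.

## Input handling

Accelerometer files (CSV `t,x,y,z` or JSON records) are resampled to a
uniform grid by linear interpolation because the FFT features require
uniform sampling and phone timestamps jitter. The grid step is the
*lower median* of the native inter-sample intervals — the order statistic,
not the midpoint average — so that for a trace whose intervals are mostly
short with occasional gaps, the denser native rate wins and no information
is discarded. Time origins are shifted to zero: every downstream feature
depends only on relative timing. Units (g or m/s²) are recorded but never
converted; all amplitude-valued features are scale-covariant and are
z-scored later anyway.

Tap events outside the 20 s test window are dropped with a logged count.
Audio is PCM WAV; stereo is averaged to mono, integer PCM divided by
2^(bits−1). A clip outside 8–12 s is flagged, not rejected, since every
acoustic measure still applies.

When a participant has several recorded trials of an activity, exactly one
is kept, chosen uniformly at random under a fixed seed — repeated sessions
would otherwise overweight that person's idiosyncrasies. The train/test
split is stratified by diagnosis label with per-class largest-remainder
quotas, so class proportions in each part match the cohort to within one
participant. The split mechanism and its default seed (20250404) are
package choices; only the split sizes are externally specified.

## Motion features

Time-domain statistics use the population (divisor-N) standard deviation
throughout; this matches the numpy default and avoids silent N−1 drift
between implementations. Spectra are computed on the *magnitude* series
√(x²+y²+z²) with the DC bin removed first — gravity dominates raw
magnitude and carries no movement information. No window or detrending is
applied by default (a Hann option exists); the spectra are summaries, not
estimators of narrowband power.

Two of the four spectral summaries need disambiguation because the common
names are overloaded:

* spectral centroid — amplitude-weighted mean frequency, Σf·A / ΣA;
* mean frequency — power-weighted, Σf·A² / ΣA².

Both reduce to f₀ for a pure tone, which is what the sinusoid tests pin
down. Spread is the amplitude-weighted standard deviation about the
centroid; the amplitude weights cancel between numerator and denominator,
so spread (like every Hz-valued feature) is invariant under amplitude
scaling.

A "repeated tap" is a consecutive pair of events on the same button — an
alternation failure. Tap consistency is the population SD of successive
inter-tap intervals, zero when fewer than three taps exist.

## Voice features

Frames are 40 ms Hann windows hopped by 10 ms. The pitch tracker is
normalized autocorrelation (unbiased estimate: the (L−k)/L taper is
divided out) with parabolic lag interpolation and a 0.3 voicing threshold.
Candidate lags carry a 0.1-per-octave log-lag penalty: a perfectly
periodic signal peaks equally at every multiple of its period, and without
the penalty the tracker locks onto subharmonics in noisy material. The
penalty only biases selection between near-tied peaks; voicing decisions
use the unpenalized peak value.

HNR is 10·log₁₀(r/(1−r)) at the parabolic-interpolated pitch-lag peak,
averaged over voiced frames and capped at 40 dB. The interpolated vertex
is used because very harmonic signals have autocorrelation peaks sharp
enough that the integer lag alone biases the ratio several dB low; the
price is a few dB of optimism at very high HNR, which none of the
ordering-based uses is sensitive to.

Shimmer is the mean |20·log₁₀(A_{i+1}/A_i)| over cycle peak amplitudes.
Cycle peaks are local maxima of |x| at least 0.7 pitch periods apart,
anchored on the waveform rather than walked on a fixed period grid — a
grid walk accumulates phase drift over a 10 s clip and washes the estimate
out.

CPPs follows the usual construction: per-frame real cepstra of the dB
magnitude spectrum, smoothed across 7 frames and 5 quefrency bins, peak in
the 2–20 ms quefrency band minus the linear regression trend fitted from
1 ms up. Cepstral values are doubled so the peak reads as the comb-ripple
amplitude of the log spectrum in dB; the measure is then amplitude-scale
invariant by construction.

GNE resamples to 10 kHz, inverse-filters with order-13 LPC (autocorrelation
method) so voiced excitation appears as a broadband pulse train, and takes
the maximum cross-correlation between Hilbert envelopes of 3 kHz bands
stepped by 500 Hz (pairs at least half a bandwidth apart), averaged over
100 ms segments.

H1−H2 uses parabolic-interpolated spectral peaks at f₀ and 2f₀ of the
whole-clip spectrum. The high-frequency noise measure is the energy
fraction above 6 kHz (missing when the sample rate cannot observe 6 kHz).
"Power spectral density" as a breathiness input is operationalized as the
mean Welch level in 0–1 kHz minus 1–5 kHz, in dB, and is exposed for
substitution.

The Acoustic Breathiness Index is an affine combination of the component
measures. The shipped coefficient set is a package default chosen for
directionality (harmonicity measures enter negatively, noise and
perturbation measures positively); it is configuration, not a claim about
any published calibration — the testable contract is the component
extraction, and any externally calibrated coefficient vector can be
supplied.

MFCCs use a 26-filter mel bank and 13 DCT-II coefficients per frame,
aggregated per clip as per-coefficient means and SDs (26 values). The
frame-to-participant aggregation is a package choice. PCA to 10
components is fitted on training rows only — fitting on everything would
leak test structure into the features and flatter the test metrics.

## Selection and kernel construction

Standardization uses training means and population SDs; missing values are
imputed with training medians first (logged), all-missing and constant
columns are dropped with a warning. Forest importances (500 trees, fixed
seed) are normalized to sum 1. The percentile cut is the
linear-interpolation percentile with inclusive (≥) comparison, so a fully
tied importance vector keeps everything; the cut (default 80) and the ×10
angle scale are configuration. The transform order is fixed as
standardize → ×importance → reorder by importance (ties broken by name) →
×10, with a config switch for the alternative order. Angles exceeding |π|
after scaling are logged as a data-quality warning, since the cos²
overlap wraps around.

Softmax measurement weights are computed over the *selected* features'
raw importances at temperature 1 — they are the per-qubit measurement
weights and must sum to 1 over the encoded qubits. Softmax is invariant
to adding a constant to all importances, so normalization convention
upstream cannot change the weights.

The kernel is K(a,b) = Σᵢ wᵢ·cos²((aᵢ−bᵢ)/2): the probability of
measuring |0⟩ after R_Y(aᵢ)·R_Y(−bᵢ) on |0⟩, aggregated by the weights.
Because every term is (1+cos Δ)/2 — a positive-definite function — and the
weights are positive, every Gram matrix is PSD; the train-Gram validator
enforces symmetry to 1e−10, unit diagonal to 1e−10 and minimum eigenvalue
≥ −1e−8. Kernels are computed analytically; a seeded shot-sampling mode
(binomial noise per qubit) exists for study but is off by default. A
config flag switches the measurement semantics to ⟨Z⟩ = cos Δ for
comparison.

Given matched weights the kernel is permutation-invariant in the features:
reordering columns together with their weights cannot change any Gram
entry (property-tested). The importance ordering of columns is therefore
a presentation convention, not a modelling degree of freedom — the number
of encoded qubits follows the selection mask, whatever it is.

### Decomposition diagnostic

A widely printed ZSX-style sequence for R_Y — RZ(−π/2), √X, RZ(θ), √X,
RZ(−π/2) in circuit order — does *not* reproduce R_Y(θ): its |0⟩
probability is sin²(θ/2), the complement of the R_Y outcome (at θ=0 it
maps |0⟩ to |1⟩). `verify_ry_decomposition` computes both outcomes, flags
the disagreement, and verifies the canonical decomposition
SX·RZ(π−θ)·SX·RZ(π) (matrix order) against R_Y(θ) to 1e−12 up to global
phase. The package implements the similarity semantics (identical inputs
→ overlap 1), which the narrative description of the kernel fixes
unambiguously.

### Benchmark kernels

The Z feature map (per-qubit H then P(2x), repeated; no entangler)
factorizes, so its fidelity is computed per qubit and multiplied. The ZZ
feature map adds linear-chain CX·P(2(π−xᵢ)(π−xⱼ))·CX entanglers and runs
through the statevector simulator (≤ 20 qubits); reps = 2 by default as
the common construction. Both are benchmark conventions, configurable.
The benchmark suite can run them on a reduced subset (default first 30
train / 15 test rows) because entangled statevector Grams are expensive.

## Classifier and evaluation

The SVM solves the soft-margin dual on the precomputed Gram with C = 1 —
the kernel itself has no free hyperparameters, and C is exposed in config
rather than tuned. Decision scores are Σ αᵢyᵢK(x,xᵢ)+b; a zero score ties
to the positive (PD) class. ROC-AUC uses continuous decision scores via
the Mann-Whitney rank statistic with ties counted half. Ratios with zero
denominators are reported missing, never zero. McNemar is the exact
two-sided binomial test, p = min(1, 2·P(X ≤ min(b,c))) with X ~
Binomial(b+c, ½); a χ² variant is available by flag.

## Synthetic cohort

The generator defines the study conditions for every end-to-end test; its
parameters are design choices, documented here, and the acceptance
properties are separation, recovery and null calibration — never a claim
to match any real cohort's feature distributions.

* **Demographics** — labels alternate to exact balance. Age bands (<40,
  40–60, >60) are drawn from class-conditional distributions —
  control (0.25, 0.35, 0.40), patient (0.101, 0.269, 0.631) — whose 50/50
  mixture reproduces the reference marginals (34, 60, 100)/194, making
  P(disease | band) increase with age; the smoking marginal is 59/194.
* **Gait** — 30 s at 100 Hz: a 2 Hz walking sinusoid with a 0.3-amplitude
  first harmonic, Gaussian noise (σ 0.05), a 1 g gravity offset on the
  vertical axis (so the magnitude series is linear in the oscillation
  rather than rectified), and, for patients, a tremor sinusoid drawn
  uniformly from 4–6 Hz at 0.8 of the walking amplitude.
* **Tapping** — alternating events with lognormal inter-tap intervals
  (positive, right-skewed): control mean 0.18 s, CV 0.1; patient 0.35 s,
  CV 0.35. Each event repeats the previous button with probability 0.02
  (control) / 0.15 (patient). The accelerometer trace carries a decaying
  8 Hz transient per tap plus the patient tremor line.
* **Voice** — 10 s at 16 kHz: a 6-harmonic source with 1/k rolloff at an
  f₀ drawn per gender (male 100–130 Hz, female 180–220 Hz), per-cycle
  Gaussian jitter (% of period) and shimmer (the √π/2 scaling makes the
  expected consecutive-cycle dB difference equal the injected value),
  plus white noise scaled to a target HNR: control 0.3 % / 0.3 dB / 25 dB,
  patient 1.5 % / 1.2 dB / 12 dB. Amplitude segments are indexed by
  accumulated phase, switching mid-cycle, so cycle peaks stay within one
  amplitude segment.

A patient profile must be at least as impaired as the control profile in
every configured dimension (checked at load). `null_profiles()` gives
both classes identical generative parameters, which must drive the
pipeline to chance — the null calibration that guards against label
leakage anywhere in the machinery.

What the generator does **not** emulate: biophysical gait dynamics (heel
strikes, stride asymmetry), vocal-tract formant structure, device
artefacts (clipping, dropouts), missing modalities, co-morbidities, or
realistic feature correlations across modalities. A pipeline that passes
the synthetic tests is verified as machinery — correct formulas, no
leakage, sane orderings — not validated as a clinical classifier.

## Problem sizes and numerics

The shipped test suite and reproduction script run the full cohort at its
reference size (n = 194, 164/30 split) with 10 s voice clips and 30 s gait
traces; unit and property tests use shorter clips and smaller cohorts,
chosen so each test pins one property with the least computation that
still exercises it. Degenerate inputs are handled explicitly: all-zero
spectra flag and zero their summaries, silent frames contribute zero
descriptors, unvoiced clips report missing pitch-dependent measures, and
empty tap series return zeros with a flag. All simulator comparisons are
at 1e−12; Gram invariants at 1e−10/−1e−8.

## Known limitations

* The synthetic task is far easier than the clinical one; default-effect
  accuracy near 1.0 says nothing about real-world accuracy.
* The ABI default coefficients are directional placeholders, not a
  clinical calibration.
* HNR is biased a few dB optimistic at very high harmonicity (vertex
  interpolation) and the measure saturates at the 40 dB cap.
* GNE carries little contrast under the 6-harmonic synthesis family,
  whose excitation is narrowband below ~1.3 kHz; it is retained because
  it applies unchanged to real broadband phonation.
* A single train/test split (no cross-validation) mirrors the evaluation
  design this pipeline reproduces and inherits its variance.
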
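# Methods

## Signal model and preprocessing

All analysis operates on mono segments of exactly 2 s at 8 kHz
(16 000 samples). Multi-channel WAV input is mixed down by channel
averaging — lossless for the common case of duplicated stethoscope
channels. Resampling is polyphase (`scipy.signal.resample_poly`) with its
built-in anti-alias low-pass; the output length is forced to
`round(n · target/source)` by trimming or zero-padding at most one
sample. Segmentation is verbatim slicing from sample 0 with no silence
trimming; a trailing partial segment is dropped rather than padded,
because padding would bias the envelope and periodicity features toward
silence. Amplitude is left untouched at read time; each segment is
peak-normalized (max |x| = 1) at the start of feature extraction, which
makes every feature invariant to recording gain.

## Features (134 per segment)

Canonical order: `mean_peak_distance`, `frequency_ratio`,
`envelope_peak_ratio`, `wavelet_energy_1..5`, `spectral_entropy`,
`zero_crossing_rate`, `mfcc_1..124`.

**Envelope features.** The envelope is the magnitude of the analytic
(Hilbert) signal smoothed by a 50 ms moving average. Peaks are local
maxima above mean + 1 SD of the envelope with a 100 ms minimum
separation — parameters chosen to resolve S1 and S2 at physiological
heart rates while ignoring ripple. `mean_peak_distance` is the mean
inter-peak interval in seconds, falling back to the segment duration
(2 s) when fewer than two peaks exist, so continuous sounds get a large,
finite value. `envelope_peak_ratio` is mean envelope height at peaks over
mean envelope overall (1.0 when no peaks): near 1 for continuous lung
noise, ≫ 1 for sparse bowel bursts.

**Zero-crossing rate** counts sign changes over N−1 sample pairs; exact
zeros inherit the previous sign so silence does not register crossings.

**Frequency ratio** is the bounded proportion E_low/(E_low + E_high) with
bands 20–200 Hz and 200–1000 Hz, computed from the one-sided power
spectrum. The low band captures heart-sound energy, the high band breath
noise and bowel bursts. The bounded form avoids division by zero; when
both bands hold only numerical leakage (≤ 1e−12 of total power) the
uninformative value 0.5 is returned and logged.

**Spectral entropy** is the Shannon entropy of the normalized one-sided
power spectrum divided by log(#bins): ~0 for a tonal line, 1 for a flat
spectrum. An all-zero segment returns 0 (logged).

**Wavelet energies** come from a 4-level Daubechies-4 decomposition with
periodized boundaries, which keeps the transform orthogonal so band
energies satisfy Parseval (verified to 1e−6 relative in tests). The five
values are the relative energies of [a4, d4, d3, d2, d1], i.e. roughly
[0–250, 250–500, 500–1000, 1000–2000, 2000–4000] Hz at 8 kHz; they are
non-negative and sum to 1. db4 is the customary biosignal default, and
normalized energies give a testable sum-to-one invariant.

**MFCC block.** 32 ms Hamming windows with 0.5 overlap give 124 frames
per 2 s segment (frame 256 samples, hop 128, no padding, frame i starting
at sample i·hop). Per frame: one-sided power spectrum → 26 unit-height
triangular mel filters spanning 0 Hz–Nyquist → log with floor 1e−10 →
orthonormal DCT-II keeping 13 coefficients. The published feature count
(124 MFCC entries at 13 coefficients per window) is dimensionally
ambiguous — 124 windows × 13 coefficients is 1612 values — so the default
reduces each window's 13 coefficients to their arithmetic mean, yielding
one value per window and preserving the 134-entry vector that downstream
counts depend on. `mfcc_block(w, full_matrix=True)` (or
`extract_features(w, mfcc_full=True)`) exposes the unreduced 124×13
matrix. Filterbank size, window type, DCT normalization, and log floor
are field-standard speech-processing defaults; the implementation is
verified against an independent naive-DFT reference to 1e−3 per
coefficient.

## Synthetic data

The generator emulates the phenomenology that separates the three organ
sounds, not their physiology:

- **heart**: two Gaussian-windowed sinusoid bursts per 0.8 s cycle
  (S1 ≈ 40 Hz / 60 ms, S2 ≈ 60 Hz / 40 ms at +0.30 s, S2 gain 0.7);
- **lung**: 4th-order Butterworth band-passed white noise (150–1000 Hz)
  amplitude-modulated by a raised sinusoid with a 4 s breath period and
  0.8 modulation depth;
- **bowel**: Poisson-arriving 20 ms tone bursts (mean 1.5/s, 200–600 Hz)
  over a faint noise floor; the arrival count is clamped to at least one
  burst, since a "bowel" segment containing no sound would be an unusable
  training label;
- **noise**: plain white noise.

White noise is added to reach a configurable SNR (default 20 dB, a
realistic electronic-stethoscope condition) and the result is
peak-normalized. Each dataset waveform derives an independent RNG stream
from (seed, index), so generation is bit-reproducible and
order-independent; per-waveform parameter jitter (beat period
0.65–0.95 s, band edges, burst rates, etc.) keeps segments non-identical
within a class.

What passing tests therefore show: the pipeline's plumbing, feature
definitions, balancing, selection, and classifiers behave correctly on
signals with the documented spectral/temporal signatures. What they do
not show: performance on real recordings, which add inter-patient
variability, sensor coloration, ambient noise, and overlapping organ
sounds. The synthetic classes are deliberately well separated —
classifiers reach macro-F1 1.0 at 20 dB SNR — so synthetic accuracy
should be read as a correctness check, not a clinical benchmark.

## Data processing

Holdout: 20 segments per class (seeded, without replacement) are removed
before anything else and only ever transformed with saved parameters.

SMOTE is implemented directly from its definition: each synthetic point
is x + u·(x_nn − x), u ~ U(0,1), between a minority row and one of its
k = 5 nearest minority neighbors (k reduced to class size − 1);
originals are preserved verbatim and synthetic rows carry a flag. Every
class is grown to the majority count.

Normalization is per-column z-scoring with population SD; zero-variance
columns are flagged and mapped to 0. The fitted (μ, σ) are serialized to
JSON and reapplied to validation and test data.

Feature selection applies five rules in order: (1) > 60 % missing,
(2) single unique value, (3) |Pearson r| ≥ 0.995 collinear pairs — the
later column in canonical order is dropped, a deterministic tie-break,
(4) zero gradient-boosting importance, (5) features outside the minimal
importance-ranked prefix reaching 0.99 cumulative normalized importance.
Importance is the gain importance of a LightGBM regressor fitted to
integer-encoded class labels (100 estimators), averaged over 10 seeded
fits; `min_child_samples` is lowered to 5 so trees can split on pools of
a few hundred rows. The acoustic features never contain missing values by
construction, so rule 1 is exercised on injected-NaN fixtures in tests.

The default stage order (holdout → SMOTE → normalize → select → split)
lets balancing and selection see the future validation fold; it is kept
as the default for protocol fidelity, and the `sound-practice` order
(split first, fit everything on the training fold) is a flag. Run
manifests record which order ran.

The 70/30 split is stratified and seeded, with per-class training counts
fixed to round(0.7·n) exactly (e.g. 103 → 72/31).

## Models

All six classifiers are fixed configurations without tuning: linear-kernel
SVM (one-vs-one, the standard reduction for margin classifiers);
MLP with one hidden layer of 10 ReLU units, softmax/cross-entropy, Adam
at lr 1e−3, at most 500 epochs with plateau stopping (tol 1e−6 over 20
epochs) and seeded initialization; 1-NN with Euclidean distance on the
normalized features; Gini decision tree with no depth cap and min leaf 1;
kernel naive Bayes with per-class, per-feature Gaussian KDEs (Silverman
bandwidth, narrow-Gaussian fallback for within-class constant features);
random forest with 100 bootstrap trees and √p features per split (size
exposed in the model spec). Training is seed-reproducible.

Prediction minimizes expected cost under a K×K cost matrix; the default
symmetric 0/1 matrix makes this exactly argmax, so posterior estimates
are only computed when a non-default matrix is supplied.

## Evaluation

Per-class metrics use the one-vs-rest reduction; zero-denominator cases
return 0 with a flag instead of raising, which degenerate synthetic
fixtures require. The summary reports accuracy (= micro-averaged
sensitivity, an identity used as a cross-check in tests), macro-F1, the
generalized multi-class MCC in covariance form, and Cohen's kappa, all
verified against scikit-learn on random confusion matrices to 1e−12.
Both macro- and micro-averaged sensitivity/specificity/precision are
reported, labeled by mode, because published summaries of this kind of
experiment are often ambiguous about the averaging convention. Train and
predict wall-times are recorded in reports but are hardware-dependent and
never asserted.

## Problem sizes

The shipped experiment uses 100 two-second segments per class at 20 dB
SNR (300 segments, 60 blinded, 168/72 train/validation), which exercises
every stage in a few seconds on one CPU; the generator scales to
arbitrary counts.

## Known limitations

- Only normal (non-pathological) sound morphologies are modeled; no
  murmurs, wheezes, crackles, or adventitious sounds.
- No denoising stage; robustness to ambient noise is only what the
  features provide.
- WAV is the only supported container.
- The paper-order pipeline intentionally reproduces a leakage-prone
  protocol; use `sound-practice` for honest validation estimates.
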
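"""Multi-domain acoustic features for 2-second auscultation segments.

Each segment is summarized by a 134-entry vector drawn from four domains:

* time — mean peak distance, envelope peak ratio, zero-crossing rate;
* frequency — frequency ratio (low/high band energy proportion), spectral
  entropy;
* time–frequency — 5 discrete-wavelet sub-band energy proportions;
* cepstral — a 124-entry MFCC block (one value per 32 ms analysis window,
  the mean of that window's 13 cepstral coefficients; the full 124x13
  coefficient matrix is available via ``full_matrix=True``).

Canonical column order is ``[mean_peak_distance, frequency_ratio,
envelope_peak_ratio, wavelet_energy_1..5, spectral_entropy,
zero_crossing_rate, mfcc_1..124]``.  Every feature is computed after
peak-normalizing the segment to max ``|x| = 1``, which makes the whole
vector invariant to recording gain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pywt
from scipy.fft import dct, rfft
from scipy.signal import find_peaks, get_window, hilbert

from .audio_io import AudioValidationError, Waveform

logger = logging.getLogger(__name__)

# Analysis-window geometry (32 ms windows, half-overlapping).
WINDOW_SECONDS = 0.032
WINDOW_OVERLAP = 0.5

# Mel filterbank and cepstrum sizes; field-standard speech defaults.
N_MEL_FILTERS = 26
N_CEPSTRA = 13
LOG_FLOOR = 1e-10

# Wavelet decomposition: Daubechies-4 over 4 levels -> 5 sub-bands.
WAVELET = "db4"
WAVELET_LEVELS = 4

# Envelope smoothing and peak-picking conventions.
ENVELOPE_SMOOTH_S = 0.050
PEAK_MIN_SEPARATION_S = 0.100

# Band edges (Hz) for the frequency-ratio proportion E_low/(E_low+E_high).
FREQ_RATIO_LOW = (20.0, 200.0)
FREQ_RATIO_HIGH = (200.0, 1000.0)


def feature_names(n_mfcc: int = 124) -> list[str]:
    """Canonical ordered feature identifiers."""
    return (
        ["mean_peak_distance", "frequency_ratio", "envelope_peak_ratio"]
        + [f"wavelet_energy_{i}" for i in range(1, 6)]
        + ["spectral_entropy", "zero_crossing_rate"]
        + [f"mfcc_{i}" for i in range(1, n_mfcc + 1)]
    )


# ---------------------------------------------------------------------------
# Framing and the MFCC block
# ---------------------------------------------------------------------------

def frame_signal(w: Waveform, window_s: float = WINDOW_SECONDS,
                 overlap: float = WINDOW_OVERLAP) -> np.ndarray:
    """Slice a waveform into half-open analysis frames, no padding.

    Frame length is ``round(window_s * rate)`` samples, hop is
    ``frame * (1 - overlap)``, and frame ``i`` starts at sample ``i * hop``
    (0-based).  A 2 s segment at 8 kHz with 32 ms windows at 0.5 overlap
    yields 124 frames of 256 samples.

    Returns an array of shape ``(n_frames, frame_length)``.
    """
    frame_len = int(round(window_s * w.rate))
    if frame_len < 1 or frame_len > len(w):
        raise AudioValidationError(
            f"window of {frame_len} samples does not fit signal of {len(w)}")
    hop = int(round(frame_len * (1.0 - overlap)))
    n_frames = (len(w) - frame_len) // hop + 1
    starts = np.arange(n_frames) * hop
    return np.stack([w.samples[s : s + frame_len] for s in starts])


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m) / 2595.0) - 1.0)


def mel_filterbank(n_filters: int, n_fft: int, rate: float,
                   f_min: float = 0.0, f_max: float | None = None) -> np.ndarray:
    """Triangular mel filterbank over the one-sided FFT bins.

    Returns an array of shape ``(n_filters, n_fft // 2 + 1)``.  Filter peaks
    are unit height (no area normalization), spanning ``f_min``–``f_max``
    (default 0 to Nyquist).
    """
    if f_max is None:
        f_max = rate / 2.0
    mel_points = np.linspace(_hz_to_mel(f_min), _hz_to_mel(f_max), n_filters + 2)
    hz_points = np.asarray(_mel_to_hz(mel_points))
    bin_freqs = np.arange(n_fft // 2 + 1) * rate / n_fft
    fbank = np.zeros((n_filters, bin_freqs.size))
    for i in range(n_filters):
        left, center, right = hz_points[i : i + 3]
        up = (bin_freqs - left) / max(center - left, 1e-12)
        down = (right - bin_freqs) / max(right - center, 1e-12)
        fbank[i] = np.clip(np.minimum(up, down), 0.0, None)
    return fbank


def mfcc_block(w: Waveform, full_matrix: bool = False) -> np.ndarray:
    """Cepstral block: short-time power spectra -> mel -> log -> DCT.

    Per frame: Hamming window, one-sided power spectrum, 26 triangular mel
    filters (0 Hz to Nyquist), log with floor 1e-10, orthonormal DCT-II
    keeping the first 13 coefficients.  By default the 13 coefficients of
    each frame are reduced to their arithmetic mean so a 2 s, 8 kHz segment
    yields exactly 124 values (one per window); ``full_matrix=True`` returns
    the unreduced ``(n_frames, 13)`` coefficient matrix.
    """
    if len(w) == 0:
        raise AudioValidationError("cannot compute MFCC of an empty signal")
    frames = frame_signal(w)
    window = get_window("hamming", frames.shape[1], fftbins=True)
    spectra = np.abs(rfft(frames * window, axis=1)) ** 2
    fbank = mel_filterbank(N_MEL_FILTERS, frames.shape[1], w.rate)
    mel_energies = spectra @ fbank.T
    log_mel = np.log(np.maximum(mel_energies, LOG_FLOOR))
    cepstra = dct(log_mel, type=2, norm="ortho", axis=1)[:, :N_CEPSTRA]
    if full_matrix:
        return cepstra
    return cepstra.mean(axis=1)


# ---------------------------------------------------------------------------
# Time-domain features
# ---------------------------------------------------------------------------

def zero_crossing_rate(w: Waveform) -> float:
    """Fraction of consecutive sample pairs with opposite sign.

    Exact zeros inherit the previous sample's sign so runs of silence do not
    count as crossings.
    """
    s = np.sign(w.samples)
    nz = s != 0
    if not nz.any():
        return 0.0
    # forward-fill zero signs; leading zeros take the first nonzero sign
    idx = np.where(nz, np.arange(s.size), 0)
    np.maximum.accumulate(idx, out=idx)
    filled = s[idx]
    first = np.argmax(nz)
    filled[:first] = s[first]
    return float(np.count_nonzero(filled[1:] != filled[:-1]) / (s.size - 1))


def envelope(w: Waveform) -> np.ndarray:
    """Magnitude of the analytic signal, smoothed by a 50 ms moving average."""
    env = np.abs(hilbert(w.samples))
    win = max(1, int(round(ENVELOPE_SMOOTH_S * w.rate)))
    kernel = np.ones(win) / win
    return np.convolve(env, kernel, mode="same")


def _envelope_peaks(env: np.ndarray, rate: float) -> np.ndarray:
    """Indices of envelope peaks above mean + 1 SD, >= 100 ms apart."""
    threshold = env.mean() + env.std()
    distance = max(1, int(round(PEAK_MIN_SEPARATION_S * rate)))
    peaks, _ = find_peaks(env, height=threshold, distance=distance)
    return peaks


def mean_peak_distance(w: Waveform) -> float:
    """Mean interval (s) between envelope peaks; full duration if < 2 peaks.

    Peaks are detected on the smoothed Hilbert envelope using a mean + 1 SD
    height threshold and a 100 ms minimum separation — enough to resolve S1
    and S2 at physiological heart rates.
    """
    peaks = _envelope_peaks(envelope(w), w.rate)
    if peaks.size < 2:
        return w.duration
    return float(np.mean(np.diff(peaks)) / w.rate)


def envelope_peak_ratio(w: Waveform) -> float:
    """Mean envelope height at detected peaks over mean envelope overall.

    Near 1 for continuous sounds, much greater than 1 for sparse bursty
    sounds.  Returns 1.0 when no peaks are detected or the envelope is zero.
    """
    env = envelope(w)
    mean_env = env.mean()
    if mean_env <= 0:
        logger.warning("zero envelope in %s; peak ratio degenerate", w.source_id)
        return 1.0
    peaks = _envelope_peaks(env, w.rate)
    if peaks.size == 0:
        return 1.0
    return float(env[peaks].mean() / mean_env)


# ---------------------------------------------------------------------------
# Frequency-domain features
# ---------------------------------------------------------------------------

def _power_spectrum(w: Waveform) -> tuple[np.ndarray, np.ndarray]:
    power = np.abs(rfft(w.samples)) ** 2
    freqs = np.arange(power.size) * w.rate / len(w)
    return freqs, power


def spectral_entropy(w: Waveform) -> float:
    """Shannon entropy of the normalized one-sided power spectrum, in [0,1].

    Normalized by ``log(n_bins)`` so a pure tone approaches 0 and a flat
    (impulse/white) spectrum approaches 1.  An all-zero signal returns 0.
    """
    _, power = _power_spectrum(w)
    total = power.sum()
    if total <= 0:
        logger.warning("zero-energy signal in %s; spectral entropy set to 0",
                       w.source_id)
        return 0.0
    p = power / total
    nz = p > 0
    return float(-(p[nz] * np.log(p[nz])).sum() / np.log(p.size))


def frequency_ratio(w: Waveform,
                    low_band: tuple[float, float] = FREQ_RATIO_LOW,
                    high_band: tuple[float, float] = FREQ_RATIO_HIGH) -> float:
    """Proportion of band energy in the low band: ``E_low / (E_low + E_high)``.

    Default bands are 20–200 Hz (where heart sounds live) versus
    200–1000 Hz (breath and bowel-burst energy).  Returns 0.5 when both
    bands are empty.
    """
    freqs, power = _power_spectrum(w)
    e_low = power[(freqs >= low_band[0]) & (freqs < low_band[1])].sum()
    e_high = power[(freqs >= high_band[0]) & (freqs < high_band[1])].sum()
    # guard against both bands holding only numerical leakage
    if e_low + e_high <= 1e-12 * power.sum() or power.sum() == 0:
        logger.warning("no energy in either band for %s; ratio set to 0.5",
                       w.source_id)
        return 0.5
    return float(e_low / (e_low + e_high))


# ---------------------------------------------------------------------------
# Time-frequency features
# ---------------------------------------------------------------------------

def wavelet_energies(w: Waveform) -> np.ndarray:
    """Relative energies of the 4-level Daubechies-4 DWT sub-bands.

    Decomposition uses periodized boundary handling, which keeps the
    transform orthogonal so the unnormalized band energies sum to the
    signal energy (Parseval).  Returned order is ``[a4, d4, d3, d2, d1]``
    (coarsest approximation first); values are proportions summing to 1.
    """
    min_len = pywt.Wavelet(WAVELET).dec_len * 2**WAVELET_LEVELS
    if len(w) < min_len:
        raise AudioValidationError(
            f"signal of {len(w)} samples too short for a "
            f"{WAVELET_LEVELS}-level {WAVELET} decomposition")
    coeffs = pywt.wavedec(w.samples, WAVELET, mode="periodization",
                          level=WAVELET_LEVELS)
    energies = np.array([np.sum(c**2) for c in coeffs])
    total = energies.sum()
    if total <= 0:
        logger.warning("zero-energy signal in %s; uniform wavelet energies",
                       w.source_id)
        return np.full(WAVELET_LEVELS + 1, 1.0 / (WAVELET_LEVELS + 1))
    return energies / total


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def peak_normalize(w: Waveform) -> Waveform:
    """Scale to max ``|x| = 1``; zero signals pass through unchanged."""
    peak = np.max(np.abs(w.samples))
    if peak == 0:
        return w
    return Waveform(samples=w.samples / peak, rate=w.rate, label=w.label,
                    source_id=w.source_id)


def extract_features(w: Waveform, mfcc_full: bool = False) -> pd.Series:
    """Compute the canonical feature vector of one segment.

    Returns a named :class:`pandas.Series` in canonical order — 134 entries
    for a 2 s, 8 kHz segment.  With ``mfcc_full=True`` the MFCC block is the
    flattened per-frame coefficient matrix (``frames x 13`` values) instead
    of the per-frame means.
    """
    w = peak_normalize(w)
    mfcc = mfcc_block(w, full_matrix=mfcc_full)
    if mfcc_full:
        mfcc_values = mfcc.ravel()
        mfcc_names = [f"mfcc_{f}_{c}" for f in range(1, mfcc.shape[0] + 1)
                      for c in range(1, mfcc.shape[1] + 1)]
    else:
        mfcc_values = mfcc
        mfcc_names = [f"mfcc_{i}" for i in range(1, mfcc.size + 1)]
    values = np.concatenate([
        [mean_peak_distance(w), frequency_ratio(w), envelope_peak_ratio(w)],
        wavelet_energies(w),
        [spectral_entropy(w), zero_crossing_rate(w)],
        mfcc_values,
    ])
    names = (feature_names(0)[:10] + mfcc_names)
    return pd.Series(values, index=names, name=w.source_id)


@dataclass
class FeatureMatrix:
    """Segments x features table with aligned labels and provenance.

    ``X`` is a :class:`pandas.DataFrame` whose columns are the canonical
    feature names; ``labels`` holds one class tag per row; ``synthetic``
    flags rows created by oversampling rather than extracted from audio.
    """

    X: pd.DataFrame
    labels: np.ndarray
    sources: list[str] = field(default_factory=list)
    synthetic: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.X) != len(self.labels):
            raise AudioValidationError(
                f"{len(self.X)} rows but {len(self.labels)} labels")
        if not self.sources:
            self.sources = [str(i) for i in self.X.index]
        if self.synthetic is None:
            self.synthetic = np.zeros(len(self.X), dtype=bool)
        if self.X.columns.duplicated().any():
            raise AudioValidationError("duplicate feature column names")

    def __len__(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def take(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            X=self.X.iloc[idx].reset_index(drop=True),
            labels=self.labels[idx],
            sources=[self.sources[i] for i in idx],
            synthetic=self.synthetic[idx],
        )

    def to_csv(self, path: str | Path) -> None:
        out = self.X.copy()
        out["label"] = self.labels
        out["source_id"] = self.sources
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        frame = pd.read_csv(path)
        labels = frame.pop("label").to_numpy()
        sources = frame.pop("source_id").astype(str).tolist()
        return cls(X=frame, labels=labels, sources=sources)


def build_matrix(segments: Sequence[Waveform], mfcc_full: bool = False) -> FeatureMatrix:
    """Extract features from equal-duration, equal-rate segments.

    Raises a validation error on mixed rates or durations (the feature
    layout depends on both).
    """
    if not segments:
        raise AudioValidationError("no segments provided")
    rates = {w.rate for w in segments}
    lengths = {len(w) for w in segments}
    if len(rates) > 1 or len(lengths) > 1:
        raise AudioValidationError(
            f"mixed rates {rates} or durations {lengths}; resample and "
            "re-segment first")
    rows = [extract_features(w, mfcc_full=mfcc_full) for w in segments]
    X = pd.DataFrame(rows).reset_index(drop=True)
    return FeatureMatrix(
        X=X,
        labels=np.array([w.label if w.label else "unknown" for w in segments]),
        sources=[w.source_id for w in segments],
    )
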
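"""Reading, resampling, and segmenting auscultation audio.

Recordings arrive at heterogeneous sample rates (electronic stethoscopes
commonly record at 8 or 10 kHz, contact microphones at 44.1 kHz).  The
analysis pipeline operates on fixed-length mono segments at a common rate,
so this module provides the three plumbing steps: WAV read (with mono
mixdown), polyphase resampling with anti-alias filtering, and slicing into
consecutive non-overlapping fixed-duration segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

#: Common analysis rate all recordings are brought to before feature
#: extraction.
DEFAULT_RATE = 8000

#: Duration of one analysis segment, in seconds.
DEFAULT_SEGMENT_SECONDS = 2.0

CLASS_LABELS = ("heart", "lung", "bowel", "noise")


class AudioValidationError(ValueError):
    """Raised when audio content violates a contract (empty, non-finite...)."""


@dataclass(frozen=True)
class Waveform:
    """A sampled audio signal with provenance.

    Parameters
    ----------
    samples
        Amplitude sequence (arbitrary units, mono).  Stored as float64.
    rate
        Sampling frequency in Hz; must be positive.
    label
        Optional class tag, one of ``heart``, ``lung``, ``bowel``, ``noise``.
    source_id
        Provenance string (file path, synthesis spec id, ...).
    """

    samples: np.ndarray
    rate: float
    label: str | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if self.rate <= 0:
            raise AudioValidationError(f"rate must be positive, got {self.rate}")
        if samples.ndim != 1 or samples.size == 0:
            raise AudioValidationError("samples must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(samples)):
            raise AudioValidationError("samples contain non-finite values")
        if self.label is not None and self.label not in CLASS_LABELS:
            raise AudioValidationError(
                f"label must be one of {CLASS_LABELS}, got {self.label!r}"
            )

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Length of the waveform in seconds."""
        return self.samples.size / self.rate


# PCM full-scale divisors for integer WAV encodings.
_PCM_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31,
              np.dtype(np.uint8): 2**7}


def read_wav(path: str | Path) -> Waveform:
    """Read a RIFF/WAVE file into a mono :class:`Waveform`.

    Multi-channel audio is mixed down by channel averaging.  Integer PCM
    samples are rescaled to [-1, 1); float samples pass through unchanged.

    Raises
    ------
    IOError
        If the file is missing, truncated, or not a WAV file.
    AudioValidationError
        If the file decodes to zero-length audio.
    """
    path = Path(path)
    try:
        rate, data = wavfile.read(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # scipy raises assorted ValueError subclasses
        raise IOError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise AudioValidationError(f"zero-length audio in {path}")
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned, offset binary
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _PCM_SCALE:
        samples = data.astype(np.float64) / _PCM_SCALE[data.dtype]
    else:
        samples = data.astype(np.float64)
    if samples.ndim == 2:
        samples = samples.mean(axis=1)
    return Waveform(samples=samples, rate=float(rate), source_id=str(path))


def write_wav(path: str | Path, w: Waveform) -> None:
    """Write a waveform as 16-bit PCM WAV (used for synthetic fixtures)."""
    peak = np.max(np.abs(w.samples))
    scaled = w.samples / peak if peak > 0 else w.samples
    pcm = np.round(scaled * (2**15 - 1)).astype(np.int16)
    wavfile.write(Path(path), int(round(w.rate)), pcm)


def resample(w: Waveform, target_rate: float) -> Waveform:
    """Resample to ``target_rate`` with polyphase anti-alias filtering.

    The output has ``round(len(w) * target_rate / w.rate)`` samples.  When
    the rates already match the waveform is returned unchanged.
    """
    if target_rate <= 0:
        raise AudioValidationError(f"target_rate must be positive, got {target_rate}")
    if target_rate == w.rate:
        return w
    frac = Fraction(int(round(target_rate * 1000)), int(round(w.rate * 1000)))
    out = resample_poly(w.samples, frac.numerator, frac.denominator)
    n_expected = int(round(len(w) * target_rate / w.rate))
    if out.size > n_expected:
        out = out[:n_expected]
    elif out.size < n_expected:
        out = np.pad(out, (0, n_expected - out.size))
    return replace(w, samples=out, rate=float(target_rate))


def segment(w: Waveform, seconds: float = DEFAULT_SEGMENT_SECONDS) -> list[Waveform]:
    """Slice into consecutive non-overlapping segments of fixed duration.

    Each segment carries the parent's label; ``source_id`` is suffixed with
    the segment index.  A trailing partial segment is dropped (padding would
    distort envelope and periodicity features).  Returns an empty list, with
    a logged warning, when the input is shorter than one segment.
    """
    if seconds <= 0:
        raise AudioValidationError(f"segment duration must be positive, got {seconds}")
    n_seg = int(round(seconds * w.rate))
    n_out = len(w) // n_seg
    if n_out == 0:
        logger.warning(
            "waveform %s (%.3f s) shorter than one %.3f s segment; dropped",
            w.source_id, w.duration, seconds,
        )
        return []
    return [
        replace(
            w,
            samples=w.samples[i * n_seg : (i + 1) * n_seg],
            source_id=f"{w.source_id}#seg{i}",
        )
        for i in range(n_out)
    ]
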
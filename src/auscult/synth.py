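"""Seeded generator of heart-, lung-, and bowel-like test sounds.

Each class mimics the phenomenology that distinguishes the real signals
rather than their physiology:

* **heart** — a quasi-periodic pulse train of two Gaussian-windowed sinusoid
  bursts per cycle (S1 and S2, low-frequency, ~0.8 s period);
* **lung** — continuous band-limited noise amplitude-modulated by a slow
  raised-sinusoid breath cycle;
* **bowel** — sparse, short, Poisson-arriving tone bursts over near-silence;
* **noise** — plain white noise (a no-signal control class).

White noise is added to every waveform to reach a configurable SNR, and the
result is peak-normalized.  Generation is bit-reproducible: the same spec
always yields the same samples, and datasets derive one independent RNG
stream per waveform from ``(seed, index)`` so they are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
from scipy.signal import butter, sosfilt

from .audio_io import AudioValidationError, Waveform, DEFAULT_RATE

#: Per-class default synthesis parameters.
DEFAULT_PARAMS: dict[str, dict[str, Any]] = {
    "heart": {
        "beat_period_s": 0.8,     # cardiac cycle length (75 bpm)
        "s1_freq_hz": 40.0,       # S1 burst center frequency
        "s2_freq_hz": 60.0,       # S2 burst center frequency
        "s1_width_s": 0.060,      # S1 Gaussian burst width
        "s2_width_s": 0.040,      # S2 Gaussian burst width
        "s2_offset_s": 0.30,      # systolic S1->S2 interval
        "s2_gain": 0.7,           # S2 amplitude relative to S1
    },
    "lung": {
        "band_hz": (150.0, 1000.0),  # vesicular breath-noise passband
        "breath_period_s": 4.0,      # respiratory cycle (15 breaths/min)
        "mod_depth": 0.8,            # AM depth of the breath cycle
    },
    "bowel": {
        "burst_rate_per_s": 1.5,     # mean Poisson arrival rate
        "burst_duration_s": 0.020,   # single click/burst length
        "burst_band_hz": (200.0, 600.0),  # burst tone frequency range
        "floor": 0.005,              # background level before SNR noise
    },
    "noise": {},
}


@dataclass(frozen=True)
class SynthSpec:
    """Full recipe for one synthetic waveform.

    Identical specs produce bit-identical waveforms.  ``params`` overrides
    entries of :data:`DEFAULT_PARAMS` for the chosen class.
    """

    klass: str
    duration: float = 2.0
    rate: float = DEFAULT_RATE
    seed: int = 0
    snr_db: float = 20.0
    params: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.klass not in DEFAULT_PARAMS:
            raise AudioValidationError(
                f"unknown class {self.klass!r}; expected one of {tuple(DEFAULT_PARAMS)}"
            )
        if self.duration <= 0 or self.rate <= 0:
            raise AudioValidationError("duration and rate must be positive")

    def resolved_params(self) -> dict[str, Any]:
        merged = dict(DEFAULT_PARAMS[self.klass])
        merged.update(self.params)
        return merged


def _gaussian_burst(t: np.ndarray, center: float, width: float, freq: float,
                    phase: float) -> np.ndarray:
    """Sinusoid under a Gaussian envelope; width is the envelope sigma."""
    env = np.exp(-0.5 * ((t - center) / width) ** 2)
    return env * np.sin(2.0 * np.pi * freq * (t - center) + phase)


def _heart(t: np.ndarray, p: Mapping[str, Any], rng: np.random.Generator) -> np.ndarray:
    x = np.zeros_like(t)
    period = p["beat_period_s"]
    n_beats = int(np.ceil(t[-1] / period)) + 1
    for k in range(n_beats):
        t1 = k * period
        x += _gaussian_burst(t, t1, p["s1_width_s"] / 2, p["s1_freq_hz"],
                             rng.uniform(0, 2 * np.pi))
        x += p["s2_gain"] * _gaussian_burst(
            t, t1 + p["s2_offset_s"], p["s2_width_s"] / 2, p["s2_freq_hz"],
            rng.uniform(0, 2 * np.pi))
    return x


def _lung(t: np.ndarray, p: Mapping[str, Any], rng: np.random.Generator,
          rate: float) -> np.ndarray:
    lo, hi = p["band_hz"]
    sos = butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    noise = sosfilt(sos, rng.standard_normal(t.size))
    phase = rng.uniform(0, 2 * np.pi)
    breath = 1.0 - p["mod_depth"] * 0.5 * (
        1.0 + np.cos(2.0 * np.pi * t / p["breath_period_s"] + phase))
    return noise * breath


def _bowel(t: np.ndarray, p: Mapping[str, Any], rng: np.random.Generator) -> np.ndarray:
    x = p["floor"] * rng.standard_normal(t.size)
    # at least one burst: a "bowel" segment with no sound at all would be an
    # unusable training label
    n_bursts = max(1, rng.poisson(p["burst_rate_per_s"] * t[-1]))
    lo, hi = p["burst_band_hz"]
    for _ in range(n_bursts):
        center = rng.uniform(0, t[-1])
        freq = rng.uniform(lo, hi)
        x += _gaussian_burst(t, center, p["burst_duration_s"] / 2, freq,
                             rng.uniform(0, 2 * np.pi))
    return x


def synth_waveform(spec: SynthSpec) -> Waveform:
    """Render one waveform from a :class:`SynthSpec`.

    The clean class signal is built first, then white noise is mixed in at
    ``spec.snr_db`` (relative to the clean signal's power), and the sum is
    peak-normalized to max ``|x| = 1``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.rate))
    t = np.arange(n) / spec.rate
    p = spec.resolved_params()
    if spec.klass == "heart":
        x = _heart(t, p, rng)
    elif spec.klass == "lung":
        x = _lung(t, p, rng, spec.rate)
    elif spec.klass == "bowel":
        x = _bowel(t, p, rng)
    else:  # noise
        x = rng.standard_normal(n)
    if spec.klass != "noise":
        sig_power = np.mean(x**2)
        noise_power = sig_power / (10.0 ** (spec.snr_db / 10.0))
        x = x + np.sqrt(noise_power) * rng.standard_normal(n)
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    return Waveform(
        samples=x, rate=spec.rate, label=spec.klass,
        source_id=f"synth:{spec.klass}:seed{spec.seed}",
    )


def _jitter(rng: np.random.Generator, klass: str) -> dict[str, Any]:
    """Random per-waveform parameter perturbations so segments differ."""
    if klass == "heart":
        return {
            "beat_period_s": rng.uniform(0.65, 0.95),
            "s1_freq_hz": rng.uniform(30.0, 55.0),
            "s2_freq_hz": rng.uniform(50.0, 80.0),
            "s2_gain": rng.uniform(0.5, 0.9),
        }
    if klass == "lung":
        lo = rng.uniform(120.0, 220.0)
        return {
            "band_hz": (lo, lo + rng.uniform(600.0, 1000.0)),
            "breath_period_s": rng.uniform(3.0, 5.0),
            "mod_depth": rng.uniform(0.6, 0.9),
        }
    if klass == "bowel":
        lo = rng.uniform(150.0, 300.0)
        return {
            "burst_rate_per_s": rng.uniform(0.8, 2.5),
            "burst_duration_s": rng.uniform(0.012, 0.035),
            "burst_band_hz": (lo, lo + rng.uniform(200.0, 500.0)),
        }
    return {}


def make_dataset(
    n_per_class: Mapping[str, int],
    seed: int = 0,
    duration: float = 2.0,
    rate: float = DEFAULT_RATE,
    snr_db: float = 20.0,
) -> list[Waveform]:
    """Generate a labeled dataset of jittered synthetic waveforms.

    ``n_per_class`` maps class name to count (use unequal counts to emulate
    an imbalanced corpus).  Each waveform gets an independent RNG stream
    derived from ``(seed, global index)``; the parameter jitter uses a
    second stream so class parameters do not interact with sample noise.
    """
    waveforms: list[Waveform] = []
    index = 0
    for klass, count in n_per_class.items():
        if count < 1:
            raise AudioValidationError(f"count for {klass!r} must be >= 1")
        if klass not in DEFAULT_PARAMS:
            raise AudioValidationError(f"unknown class {klass!r}")
        for _ in range(count):
            jit_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(index, 1)))
            wave_seed = int(
                np.random.SeedSequence(entropy=seed, spawn_key=(index, 0))
                .generate_state(1)[0] % (2**31))
            spec = SynthSpec(
                klass=klass, duration=duration, rate=rate, seed=wave_seed,
                snr_db=snr_db, params=_jitter(jit_rng, klass),
            )
            w = synth_waveform(spec)
            waveforms.append(
                Waveform(samples=w.samples, rate=w.rate, label=klass,
                         source_id=f"synth:{klass}:{index}"))
            index += 1
    return waveforms
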
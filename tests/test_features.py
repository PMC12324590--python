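"""Feature extraction against independent oracles and closed forms."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from auscult import (AudioValidationError, Waveform, build_matrix, envelope,
                     envelope_peak_ratio, extract_features, feature_names,
                     frame_signal, frequency_ratio, mean_peak_distance,
                     mfcc_block, spectral_entropy, wavelet_energies,
                     zero_crossing_rate)
from auscult.features import (LOG_FLOOR, N_CEPSTRA, N_MEL_FILTERS,
                              mel_filterbank)

RATE = 8000


def wave(x, rate=RATE):
    return Waveform(np.asarray(x, dtype=float), rate)


class TestFraming:
    @pytest.mark.parametrize("n_samples, expected", [
        (16000, 124),   # 2 s at 8 kHz: the canonical analysis geometry
        (256, 1),       # exactly one window
        (512, 3),       # starts at 0, 128, 256
    ])
    def test_frame_counts(self, n_samples, expected):
        frames = frame_signal(wave(np.arange(n_samples)))
        assert frames.shape == (expected, 256)

    def test_frames_are_half_open_hops(self):
        frames = frame_signal(wave(np.arange(512)))
        np.testing.assert_array_equal(frames[1], np.arange(128, 128 + 256))

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(AudioValidationError):
            frame_signal(wave(np.arange(100)))


def naive_mfcc(x, rate):
    """Independent cepstral reference: explicit DFT, filterbank, DCT sums."""
    frame_len = round(0.032 * rate)
    hop = frame_len // 2
    n_frames = (len(x) - frame_len) // hop + 1
    n = np.arange(frame_len)
    hamming = 0.54 - 0.46 * np.cos(2 * np.pi * n / frame_len)
    fbank = mel_filterbank(N_MEL_FILTERS, frame_len, rate)
    k = np.arange(frame_len // 2 + 1)
    dft = np.exp(-2j * np.pi * np.outer(k, n) / frame_len)
    out = []
    for i in range(n_frames):
        frame = x[i * hop : i * hop + frame_len] * hamming
        power = np.abs(dft @ frame) ** 2
        log_mel = np.log(np.maximum(fbank @ power, LOG_FLOOR))
        coeffs = []
        for q in range(N_CEPSTRA):
            m = np.arange(N_MEL_FILTERS)
            v = np.sum(log_mel * np.cos(np.pi * q * (2 * m + 1) / (2 * N_MEL_FILTERS)))
            v *= math.sqrt(1 / N_MEL_FILTERS) if q == 0 else math.sqrt(2 / N_MEL_FILTERS)
            coeffs.append(v)
        out.append(coeffs)
    return np.array(out)


class TestMfcc:
    def test_canonical_block_has_124_values(self):
        rng = np.random.default_rng(0)
        assert mfcc_block(wave(rng.standard_normal(16000))).shape == (124,)

    def test_thirteen_coefficients_per_window(self):
        rng = np.random.default_rng(0)
        full = mfcc_block(wave(rng.standard_normal(16000)), full_matrix=True)
        assert full.shape == (124, 13)

    def test_all_zero_signal_gives_constant_block(self):
        block = mfcc_block(wave(np.zeros(16000)))
        assert np.allclose(block, block[0])

    def test_bin_aligned_tone_is_stationary(self):
        """A tone on an FFT bin yields phase-coherent frames, so the
        per-window values barely vary."""
        t = np.arange(16000) / RATE
        block = mfcc_block(wave(np.sin(2 * np.pi * 312.5 * t)))
        assert np.var(block) < 1e-3 * np.mean(block**2)

    def test_agrees_with_independent_reference(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(16000)
        ours = mfcc_block(wave(x), full_matrix=True)
        ref = naive_mfcc(x, RATE)
        assert np.max(np.abs(ours - ref)) < 1e-3


class TestZeroCrossingRate:
    @pytest.mark.parametrize("x, expected", [
        (np.ones(100), 0.0),
        ([1.0, -1.0, 1.0, -1.0], 1.0),
        ([1.0, 0.0, 0.0, -1.0], 1 / 3),  # zeros inherit previous sign
    ])
    def test_known_patterns(self, x, expected):
        assert zero_crossing_rate(wave(x)) == pytest.approx(expected)

    def test_sine_matches_brute_force(self):
        t = np.arange(16000) / RATE
        x = np.sin(2 * np.pi * 100 * t)
        brute = np.count_nonzero(np.diff(np.sign(x)[np.sign(x) != 0]) != 0)
        assert zero_crossing_rate(wave(x)) == pytest.approx(brute / 15999)
        assert zero_crossing_rate(wave(x)) == pytest.approx(400 / 15999, rel=0.01)


class TestSpectralEntropy:
    def test_pure_tone_near_zero(self, tone):
        assert spectral_entropy(tone(250)) < 0.1  # bin-aligned line

    def test_impulse_is_one(self):
        x = np.zeros(1024)
        x[0] = 1.0
        assert spectral_entropy(wave(x)) == pytest.approx(1.0)

    def test_two_equal_bins_closed_form(self, time_axis):
        x = np.cos(2 * np.pi * 100 * time_axis) + np.cos(2 * np.pi * 600 * time_axis)
        expected = math.log(2) / math.log(8001)  # one-sided bins of 16000 samples
        assert spectral_entropy(wave(x)) == pytest.approx(expected, rel=1e-6)

    def test_zero_signal_defined_as_zero(self):
        assert spectral_entropy(wave(np.zeros(100))) == 0.0


class TestWaveletEnergies:
    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(5)
        e = wavelet_energies(wave(rng.standard_normal(16000)))
        assert e.shape == (5,)
        assert np.all(e >= 0)
        assert e.sum() == pytest.approx(1.0, abs=1e-9)

    def test_low_tone_concentrates_in_approximation_band(self, tone):
        e = wavelet_energies(tone(20))
        assert e[0] > 0.9  # a4 covers roughly 0-250 Hz

    def test_white_noise_splits_by_bandwidth(self):
        rng = np.random.default_rng(0)
        e = wavelet_energies(wave(rng.standard_normal(16000)))
        assert e[4] == pytest.approx(0.5, abs=0.05)  # d1 spans half the bandwidth

    def test_energy_conservation(self):
        """Orthogonal DWT: unnormalized band energies sum to signal energy."""
        import pywt
        rng = np.random.default_rng(3)
        x = rng.standard_normal(16000)
        coeffs = pywt.wavedec(x, "db4", mode="periodization", level=4)
        band_total = sum(np.sum(c**2) for c in coeffs)
        assert band_total == pytest.approx(np.sum(x**2), rel=1e-6)

    def test_too_short_signal_rejected(self):
        with pytest.raises(AudioValidationError):
            wavelet_energies(wave(np.ones(16)))


class TestEnvelope:
    def test_constant_signal(self):
        env = envelope(wave(np.full(16000, 0.7)))
        interior = env[800:-800]  # away from edge transients
        assert np.allclose(interior, 0.7, atol=0.02)

    def test_tracks_known_modulator(self, time_axis):
        mod = 1 + 0.5 * np.sin(2 * np.pi * 2 * time_axis)
        env = envelope(wave(mod * np.sin(2 * np.pi * 500 * time_axis)))
        rel_rms = np.sqrt(np.mean((env - mod) ** 2)) / np.sqrt(np.mean(mod**2))
        assert rel_rms < 0.10

    def test_zero_signal_zero_envelope(self):
        assert np.all(envelope(wave(np.zeros(1000))) == 0)


class TestPeakFeatures:
    def test_regular_pulse_train_distance(self, pulse_train):
        w = pulse_train([0.25, 0.75, 1.25, 1.75])
        assert mean_peak_distance(w) == pytest.approx(0.5, abs=0.01)

    def test_hand_enumerated_intervals(self, pulse_train):
        w = pulse_train([0.1, 0.5, 1.1, 1.5])
        assert mean_peak_distance(w) == pytest.approx((0.4 + 0.6 + 0.4) / 3, abs=0.01)

    def test_flat_envelope_falls_back_to_duration(self, tone):
        assert mean_peak_distance(tone(100)) == pytest.approx(2.0)

    def test_peak_ratio_constant_envelope(self):
        assert envelope_peak_ratio(wave(np.full(16000, 0.5))) == pytest.approx(1.0)

    def test_peak_ratio_monotone_in_burst_contrast(self, pulse_train):
        low = pulse_train([0.4, 1.2], amplitude=5, floor=0.1)
        high = pulse_train([0.4, 1.2], amplitude=20, floor=0.1)
        assert envelope_peak_ratio(high) > envelope_peak_ratio(low) > 5

    def test_peak_ratio_zero_signal(self):
        assert envelope_peak_ratio(wave(np.zeros(16000))) == 1.0


class TestFrequencyRatio:
    def test_low_tone_near_one(self, tone):
        assert frequency_ratio(tone(100)) > 0.99

    def test_high_tone_near_zero(self, tone):
        assert frequency_ratio(tone(500)) < 0.01

    def test_equal_mixture_is_half(self, time_axis):
        x = np.cos(2 * np.pi * 100 * time_axis) + np.cos(2 * np.pi * 500 * time_axis)
        assert frequency_ratio(wave(x)) == pytest.approx(0.5, abs=1e-3)

    def test_out_of_band_signal_is_half(self, tone):
        assert frequency_ratio(tone(2000)) == 0.5


class TestAssembly:
    def test_vector_has_134_named_entries(self, tone):
        fv = extract_features(tone(150))
        assert len(fv) == 134
        assert list(fv.index) == feature_names()
        assert np.all(np.isfinite(fv.to_numpy()))

    def test_matrix_shape_and_labels(self):
        from auscult import make_dataset
        segs = make_dataset({"heart": 3, "lung": 2}, seed=1)
        m = build_matrix(segs)
        assert m.X.shape == (5, 134)
        assert list(m.labels) == [w.label for w in segs]

    def test_duplicate_segment_gives_identical_rows(self, tone):
        w = tone(150)
        m = build_matrix([w, w])
        np.testing.assert_array_equal(m.X.iloc[0].to_numpy(), m.X.iloc[1].to_numpy())

    def test_mixed_rates_rejected(self, tone):
        with pytest.raises(AudioValidationError):
            build_matrix([tone(100, rate=8000), tone(100, rate=10000)])

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(gain=st.floats(min_value=0.01, max_value=100.0),
           seed=st.integers(min_value=0, max_value=50))
    def test_gain_invariance(self, gain, seed):
        """Peak normalization makes every feature gain-invariant."""
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(16000)
        base = extract_features(wave(x)).to_numpy()
        scaled = extract_features(wave(gain * x)).to_numpy()
        np.testing.assert_allclose(scaled, base, rtol=1e-6, atol=1e-9)
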
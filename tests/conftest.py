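import numpy as np
import pytest

from auscult import Waveform

RATE = 8000
T = np.arange(2 * RATE) / RATE


@pytest.fixture
def time_axis():
    """Two seconds of sample times at the 8 kHz analysis rate."""
    return T


@pytest.fixture
def tone():
    """Factory for pure 2 s tones at the analysis rate."""

    def make(freq, amplitude=1.0, rate=RATE):
        t = np.arange(2 * rate) / rate
        return Waveform(amplitude * np.sin(2 * np.pi * freq * t), rate)

    return make


@pytest.fixture
def pulse_train():
    """Factory for Gaussian-windowed tone bursts at given centers (s)."""

    def make(centers, width=0.02, carrier=200.0, amplitude=1.0, floor=0.0):
        x = floor * np.sin(2 * np.pi * 150 * T)
        for c in centers:
            x = x + amplitude * np.exp(-0.5 * ((T - c) / width) ** 2) * np.sin(
                2 * np.pi * carrier * T)
        return Waveform(x, RATE)

    return make


@pytest.fixture
def feature_blobs():
    """Small separable 3-class feature matrix for model tests."""
    import pandas as pd
    from auscult import FeatureMatrix

    rng = np.random.default_rng(42)
    centers = {"heart": [0, 0, 0, 0], "lung": [4, 4, 0, 0], "bowel": [0, 4, 4, 4]}
    rows, labels = [], []
    for klass, c in centers.items():
        rows.append(rng.normal(c, 0.4, size=(30, 4)))
        labels += [klass] * 30
    X = pd.DataFrame(np.vstack(rows), columns=[f"f{i}" for i in range(4)])
    return FeatureMatrix(X=X, labels=np.array(labels))
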
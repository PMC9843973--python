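import numpy as np
import pandas as pd
import pytest

from mycoftir.spectral_core import Spectrum, SpectrumCollection, WavenumberAxis


@pytest.fixture
def axis():
    return WavenumberAxis(np.arange(1000.0, 1800.0, 4.0))


@pytest.fixture
def gaussian_spectrum(axis):
    v = axis.values
    y = np.exp(-0.5 * ((v - 1400.0) / 20.0) ** 2)
    return Spectrum(axis, y, {"technique": "HTS"})


@pytest.fixture
def small_collection(axis):
    rng = np.random.default_rng(42)
    base = np.exp(-0.5 * ((axis.values - 1400.0) / 30.0) ** 2)
    rows = [base * (1 + 0.1 * i) + rng.normal(0, 0.01, len(axis)) for i in range(6)]
    meta = pd.DataFrame(
        {
            "spectrum_id": [f"s{i}" for i in range(6)],
            "sample": ["A", "A", "A", "B", "B", "B"],
            "replicate": [1, 2, 3, 1, 2, 3],
            "day": [1, 1, 1, 1, 1, 1],
        }
    )
    return SpectrumCollection(axis, np.vstack(rows), meta)
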
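import numpy as np
import pandas as pd
import pytest

from oxishelf.config import SyntheticConfig
from oxishelf.dataset import SpectralDataset
from oxishelf.synthetic import make_study


@pytest.fixture(scope="session")
def default_config() -> SyntheticConfig:
    return SyntheticConfig(seed=11)


@pytest.fixture(scope="session")
def default_study(default_config):
    """One shared full-size synthetic study (78 spectra)."""
    return make_study(default_config)


@pytest.fixture()
def tiny_dataset() -> SpectralDataset:
    """3 samples x 8 channels with simple known values."""
    wn = np.linspace(1000.0, 1700.0, 8)
    A = np.array(
        [
            np.linspace(1.0, 8.0, 8),
            2.0 * np.linspace(1.0, 8.0, 8) + 5.0,
            np.sin(wn / 300.0) + 2.0,
        ]
    )
    meta = pd.DataFrame(
        {
            "sample_id": ["a", "b", "c"],
            "process": ["DP", "DP", "HP"],
            "temperature_C": [30.0, 40.0, 50.0],
            "day": [0.0, 5.0, 10.0],
            "replicate": [1, 2, 3],
        }
    )
    return SpectralDataset(wavenumbers=wn, absorbance=A, metadata=meta)
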
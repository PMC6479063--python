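import numpy as np
import pytest

import rootnir as rn
from rootnir.spectra import SpectraMatrix


@pytest.fixture(scope="session")
def small_dataset():
    """Default-condition synthetic study at the field sample size (74)."""
    cfg = rn.SyntheticConfig(seed=2024)
    comps, spectra, reference = rn.simulate_dataset(cfg)
    return cfg, comps, spectra, reference


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def random_spectra(rng):
    """Unstructured random spectra for shape/identity checks."""
    grid = np.linspace(800.0, 2500.0, 40)
    values = rng.normal(0.5, 0.1, size=(6, 40))
    return SpectraMatrix([f"s{i}" for i in range(6)], grid, values)
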
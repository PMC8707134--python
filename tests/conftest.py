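import numpy as np
import pytest

from fieldspec.design import generate_design
from fieldspec.preprocess import META_COLUMNS, SpectrumSet
from fieldspec.simulate import WAVELENGTH_GRID, simulate_trial


@pytest.fixture(scope="session")
def default_design():
    """The standard 4-block, 40-plot, 480-spot layout (seed 1)."""
    return generate_design(seed=1)


@pytest.fixture(scope="session")
def synthetic_trial():
    """One full synthetic trial: (design, responses, reflectance)."""
    return simulate_trial(seed=1)


@pytest.fixture(scope="session")
def synthetic_spectrumset(synthetic_trial):
    design, responses, reflectance = synthetic_trial
    return SpectrumSet(
        wavelengths=WAVELENGTH_GRID.astype(float),
        reflectance=reflectance,
        meta=responses[META_COLUMNS].copy(),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
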
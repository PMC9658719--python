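import numpy as np
import pytest

from glycospec.spectra import Spectrum, SpectrumKind, WavelengthGrid
from glycospec.synthetic import (
    gaussian_band_spectrum,
    level1_band_model,
    nonglycated_band_model,
)


@pytest.fixture
def visible_grid() -> WavelengthGrid:
    return WavelengthGrid(450.0, 700.0, 1.0)


@pytest.fixture
def full_grid() -> WavelengthGrid:
    return WavelengthGrid(300.0, 1100.0, 1.0)


@pytest.fixture
def eps_a1c_level1(full_grid) -> Spectrum:
    return gaussian_band_spectrum(level1_band_model(), full_grid)


@pytest.fixture
def eps_non(full_grid) -> Spectrum:
    return gaussian_band_spectrum(nonglycated_band_model(), full_grid)


@pytest.fixture
def simple_transmittance() -> Spectrum:
    """Small handmade %T spectrum with convenient round values."""
    lam = np.array([500.0, 510.0, 520.0, 530.0, 540.0])
    pct = np.array([100.0, 50.0, 10.0, 1.0, 25.0])
    return Spectrum(lam, pct, SpectrumKind.PERCENT_TRANSMITTANCE)
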
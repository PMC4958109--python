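import numpy as np
import pytest

from beamkit import DEFAULT_GRID, DoseConstants, EnergyGrid, Spectrum
from beamkit.materials import MaterialLibrary, _ElementTable


@pytest.fixture
def grid():
    return DEFAULT_GRID


@pytest.fixture
def mono_spectrum():
    """Factory: monoenergetic spectrum with ``fluence`` photons in one bin."""

    def make(bin_index: int, fluence: float = 1e6, grid: EnergyGrid = DEFAULT_GRID):
        q = np.zeros(grid.n_bins)
        q[bin_index - 1] = fluence
        return Spectrum(fluence=q, grid=grid)

    return make


@pytest.fixture
def unit_dose_constants():
    """(mu_en/rho)_air = 1 cm^2/g everywhere: makes kerma hand-computable."""
    return DoseConstants(grid=DEFAULT_GRID,
                         mu_en_over_rho_air=np.ones(DEFAULT_GRID.n_bins))


@pytest.fixture
def flat_mu_library():
    """Factory: library with one element of constant mu_linear (mm^-1).

    mu/rho is constant and density 10 g/cm^3, so mu_linear == mu_over_rho
    numerically - convenient for closed-form attenuation oracles.
    """

    def make(mu_linear: float, symbol: str = "Tt", Z: int = 43):
        table = _ElementTable(
            Z=Z, symbol=symbol, density=10.0,
            energies=DEFAULT_GRID.centers.copy(),
            mu_over_rho=np.full(DEFAULT_GRID.n_bins, mu_linear),
        )
        return MaterialLibrary(elements={Z: table})

    return make
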
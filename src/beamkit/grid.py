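"""Energy-grid conventions.

All spectra and attenuation curves in the toolkit share one convention:
1 keV-wide energy bins indexed 1..n_bins, where bin ``i`` covers the
half-open interval [i, i+1) keV and all per-energy physics is evaluated at
the bin center ``i + 0.5`` keV (centers 1.5, 2.5, ... keV).  The default
diagnostic grid has 150 bins (1-151 keV); the grid is extensible by simply
constructing one with more bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EnergyGrid", "DEFAULT_GRID"]


@dataclass(frozen=True)
class EnergyGrid:
    """1 keV binning for spectra and attenuation curves.

    Parameters
    ----------
    n_bins : int
        Number of 1 keV bins; bin ``i`` (1-based) covers [i, i+1) keV.
    """

    n_bins: int = 150

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise ValueError(f"n_bins must be >= 1, got {self.n_bins}")

    @property
    def lower_edges(self) -> np.ndarray:
        """Lower bin edges in keV (1, 2, ..., n_bins)."""
        return np.arange(1, self.n_bins + 1, dtype=float)

    @property
    def centers(self) -> np.ndarray:
        """Bin centers in keV (1.5, 2.5, ..., n_bins + 0.5)."""
        return self.lower_edges + 0.5

    def bin_center(self, i: int) -> float:
        """Center energy (keV) of 1-based bin ``i``."""
        if not 1 <= i <= self.n_bins:
            raise IndexError(f"bin index {i} outside 1..{self.n_bins}")
        return i + 0.5

    def bin_of(self, energy_kev: float) -> int:
        """1-based index of the bin containing ``energy_kev``."""
        i = int(np.floor(energy_kev))
        if not 1 <= i <= self.n_bins:
            raise IndexError(f"energy {energy_kev} keV outside grid")
        return i

    def __len__(self) -> int:
        return self.n_bins


DEFAULT_GRID = EnergyGrid()
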
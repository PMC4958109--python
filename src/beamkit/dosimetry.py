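"""Beam-quality and dosimetric summary metrics.

Air kerma for a fluence spectrum q(E) [photons/mm^2/mAs at 100 cm] is the
standard mass energy-absorption integral

    K [mGy/mAs] = sum_E q(E) * 100 * E * (mu_en/rho)_air(E) * k_J / 1e-6

with E the bin-center energy in keV, (mu_en/rho)_air in cm^2/g, k_J =
1.602176e-16 J/keV, the factor 100 converting mm^-2 to cm^-2, and 1e-6
taking J/g to mGy.  Exposure follows from the air-kerma-per-roentgen
constant 8.764 mGy/R (2.58e-4 C/kg per R times W/e = 33.97 J/C).  All
constants are centralized in :class:`DoseConstants` and overridable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataValidationError, OutOfRangeError, ZeroDoseError
from .grid import DEFAULT_GRID, EnergyGrid
from .spectrum import Spectrum

__all__ = [
    "DoseConstants",
    "air_kerma",
    "exposure",
    "fluence_per_air_kerma",
    "fluence_per_exposure",
    "hvl",
    "hvl_sequence",
    "mean_energy",
    "to_pdf",
]

JOULE_PER_KEV = 1.602176e-16
MGY_PER_ROENTGEN = 8.764  # 2.58e-4 C/kg/R * 33.97 J/C, in mGy/R
MGY_PER_MR = MGY_PER_ROENTGEN * 1e-3


@dataclass
class DoseConstants:
    """Mass energy-absorption coefficient of air plus unit constants."""

    grid: EnergyGrid
    mu_en_over_rho_air: np.ndarray  # cm^2/g at grid.centers
    joule_per_kev: float = JOULE_PER_KEV
    mgy_per_roentgen: float = MGY_PER_ROENTGEN

    def __post_init__(self) -> None:
        self.mu_en_over_rho_air = np.asarray(self.mu_en_over_rho_air, dtype=float)
        if self.mu_en_over_rho_air.shape != (self.grid.n_bins,):
            raise DataValidationError("(mu_en/rho)_air length != grid n_bins")
        if np.any(self.mu_en_over_rho_air <= 0):
            raise DataValidationError("(mu_en/rho)_air must be positive")


def _constants(spectrum: Spectrum, constants: DoseConstants | None) -> DoseConstants:
    if constants is None:
        from . import fixtures
        constants = fixtures.default_dose_constants(spectrum.grid)
    if constants.grid.n_bins != spectrum.grid.n_bins:
        raise DataValidationError(
            f"grid mismatch: spectrum has {spectrum.grid.n_bins} bins, "
            f"dose table has {constants.grid.n_bins}"
        )
    return constants


def air_kerma(spectrum: Spectrum, constants: DoseConstants | None = None) -> float:
    """Air kerma in mGy/mAs at 100 cm from the source."""
    c = _constants(spectrum, constants)
    with np.errstate(over="ignore"):  # saturated tuner probes stay ordered
        kerma = np.sum(
            spectrum.fluence * 100.0 * spectrum.grid.centers
            * c.mu_en_over_rho_air * c.joule_per_kev
        ) / 1e-6
    return float(kerma)


def exposure(spectrum: Spectrum, constants: DoseConstants | None = None) -> float:
    """Exposure in mR/mAs at 100 cm from the source."""
    c = _constants(spectrum, constants)
    return air_kerma(spectrum, c) / (c.mgy_per_roentgen * 1e-3)


def fluence_per_air_kerma(spectrum: Spectrum,
                          constants: DoseConstants | None = None) -> float:
    """Total fluence per unit air kerma, photons/mm^2/mGy."""
    kerma = air_kerma(spectrum, constants)
    if kerma <= 0:
        raise ZeroDoseError("fluence per air kerma undefined for zero-dose spectrum")
    return spectrum.total_fluence / kerma


def fluence_per_exposure(spectrum: Spectrum,
                         constants: DoseConstants | None = None) -> float:
    """Total fluence per unit exposure, photons/mm^2/mR."""
    x = exposure(spectrum, constants)
    if x <= 0:
        raise ZeroDoseError("fluence per exposure undefined for zero-dose spectrum")
    return spectrum.total_fluence / x


def mean_energy(spectrum: Spectrum) -> float:
    """Fluence-weighted mean energy in keV."""
    total = spectrum.total_fluence
    if total <= 0:
        raise ZeroDoseError("mean energy undefined for zero-fluence spectrum")
    return float(np.sum(spectrum.fluence * spectrum.grid.centers) / total)


def to_pdf(spectrum: Spectrum) -> Spectrum:
    """Probability-normalized copy; bins sum to 1 exactly.

    The final nonzero bin absorbs the floating-point rounding residual.
    """
    total = spectrum.total_fluence
    if total <= 0:
        raise ZeroDoseError("cannot normalize a zero-fluence spectrum")
    pdf = spectrum.fluence / total
    last = int(np.nonzero(pdf)[0][-1])
    pdf[last] += 1.0 - pdf.sum()
    out = spectrum.copy()
    out.fluence = pdf
    return out


def hvl_sequence(spectrum: Spectrum, material: int | str = "Al", order: int = 1,
                 constants: DoseConstants | None = None, library=None,
                 rel_tol: float = 1e-9, max_thickness_mm: float = 1e4) -> list[float]:
    """Successive half-value layers [t_1, ..., t_order] in mm.

    t_n is the extra thickness that takes the air kerma of the already
    (n-1)-times-halved beam down to K0/2^n; each HVL is found by geometric
    upper-bracket growth followed by bisection to |K - target|/K0 <=
    ``rel_tol``.  Successive HVLs act on the progressively hardened beam,
    so t_2 >= t_1 whenever attenuation falls with energy (beam hardening).
    """
    from .materials import default_library

    lib = library if library is not None else default_library()
    curve = lib.resolve_any_curve(material, spectrum.grid)
    c = _constants(spectrum, constants)

    k0 = air_kerma(spectrum, c)
    if k0 <= 0:
        raise ZeroDoseError("HVL undefined for non-positive air kerma")
    fluence0 = spectrum.fluence
    mu = curve.mu_linear

    def kerma_at(t_total: float) -> float:
        filtered = Spectrum(fluence0 * np.exp(-mu * t_total), grid=spectrum.grid)
        return air_kerma(filtered, c)

    results: list[float] = []
    t_prev = 0.0
    for n in range(1, order + 1):
        target = k0 / 2.0**n
        # grow the upper bracket geometrically
        hi = t_prev + max(t_prev, 1.0)
        while kerma_at(hi) > target:
            hi = t_prev + 2.0 * (hi - t_prev)
            if hi - t_prev > max_thickness_mm:
                raise OutOfRangeError(
                    f"no HVL bracket within {max_thickness_mm} mm of {curve.material_id}"
                )
        lo = t_prev
        while True:
            mid = 0.5 * (lo + hi)
            k_mid = kerma_at(mid)
            if abs(k_mid - target) / k0 <= rel_tol or (hi - lo) < 1e-15 * max(hi, 1.0):
                break
            if k_mid > target:
                lo = mid
            else:
                hi = mid
        results.append(mid - t_prev)
        t_prev = mid
    return results


def hvl(spectrum: Spectrum, material: int | str = "Al", order: int = 1,
        constants: DoseConstants | None = None, library=None) -> float:
    """The ``order``-th half-value layer in mm (1st by default)."""
    if order < 1:
        raise DataValidationError(f"HVL order must be >= 1, got {order}")
    return hvl_sequence(spectrum, material, order, constants, library)[-1]
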
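"""Elemental and compound attenuation data.

The toolkit evaluates mass attenuation coefficients mu/rho(E) [cm^2/g] at
the energy-grid bin centers, converting to linear attenuation
mu [mm^-1] = mu/rho [cm^2/g] * rho [g/cm^3] / 10.  Interpolation between
tabulated source energies is linear in log(mu/rho) vs log(E), the standard
practice for NIST-style tables; duplicated-energy rows (absorption edges)
are honored by not interpolating across the edge.

Because the package ships no third-party tables, the *default* material
library is a synthetic analytic dataset:

    mu/rho(E) = a / E^3 + b,   a = 12 * Z^3 (keV^3 cm^2/g),  b = 0.18 cm^2/g

which captures the photoelectric E^-3 falloff plus a Compton-like plateau;
high-Z elements additionally carry a K-edge discontinuity (photoelectric
term reduced by the edge jump ratio below the edge), the feature that
makes W filtration spectrally distinguishable from Al.
It is structurally realistic (magnitudes roughly right in the diagnostic
range for light elements) but is NOT real cross-section data; real NIST
tables can be loaded through :mod:`beamkit.io` and used everywhere the
default library is.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import DataValidationError, MaterialNotFoundError
from .grid import DEFAULT_GRID, EnergyGrid

__all__ = [
    "Element",
    "AttenuationCurve",
    "CompoundSpec",
    "MaterialLibrary",
    "ELEMENTS",
    "COMPOUND_REGISTRY",
    "default_library",
    "mu_rho_element",
    "mu_rho_compound",
    "synthetic_mu_over_rho",
]

# Z: (symbol, name, atomic weight g/mol, density g/cm^3 at STP)
_ELEMENT_ROWS = [
    (1, "H", "Hydrogen", 1.008, 8.375e-5),
    (4, "Be", "Beryllium", 9.012, 1.848),
    (6, "C", "Carbon", 12.011, 2.267),
    (7, "N", "Nitrogen", 14.007, 1.165e-3),
    (8, "O", "Oxygen", 15.999, 1.332e-3),
    (9, "F", "Fluorine", 18.998, 1.580e-3),
    (11, "Na", "Sodium", 22.990, 0.971),
    (12, "Mg", "Magnesium", 24.305, 1.738),
    (13, "Al", "Aluminum", 26.982, 2.699),
    (14, "Si", "Silicon", 28.085, 2.330),
    (16, "S", "Sulfur", 32.06, 2.070),
    (18, "Ar", "Argon", 39.948, 1.662e-3),
    (20, "Ca", "Calcium", 40.078, 1.550),
    (22, "Ti", "Titanium", 47.867, 4.540),
    (26, "Fe", "Iron", 55.845, 7.874),
    (29, "Cu", "Copper", 63.546, 8.960),
    (31, "Ga", "Gallium", 69.723, 5.904),
    (32, "Ge", "Germanium", 72.630, 5.323),
    (33, "As", "Arsenic", 74.922, 5.730),
    (42, "Mo", "Molybdenum", 95.95, 10.220),
    (48, "Cd", "Cadmium", 112.414, 8.650),
    (50, "Sn", "Tin", 118.710, 7.310),
    (52, "Te", "Tellurium", 127.60, 6.240),
    (53, "I", "Iodine", 126.904, 4.930),
    (55, "Cs", "Cesium", 132.905, 1.873),
    (64, "Gd", "Gadolinium", 157.25, 7.900),
    (74, "W", "Tungsten", 183.84, 19.300),
    (82, "Pb", "Lead", 207.20, 11.350),
    (83, "Bi", "Bismuth", 208.980, 9.747),
]

# Synthetic analytic attenuation shape (see module docstring).
SYNTHETIC_A_PER_Z3 = 12.0  # keV^3 cm^2/g
SYNTHETIC_B = 0.18  # cm^2/g

# K-edge energies (keV, handbook values) for elements whose edge falls well
# inside the diagnostic range; below the edge the photoelectric term is
# divided by the edge jump ratio (K-shell not yet accessible).  Light
# elements keep the pure power-law form.
K_EDGE_KEV = {
    42: 20.000, 48: 26.711, 50: 29.200, 52: 31.814, 53: 33.169,
    55: 35.985, 64: 50.239, 74: 69.525, 82: 88.005, 83: 90.526,
}
K_EDGE_JUMP = 4.5


@dataclass(frozen=True)
class Element:
    Z: int
    symbol: str
    name: str
    atomic_weight: float
    density: float  # g/cm^3


ELEMENTS: dict[int, Element] = {row[0]: Element(*row) for row in _ELEMENT_ROWS}
_SYMBOL_TO_Z: dict[str, int] = {e.symbol.lower(): e.Z for e in ELEMENTS.values()}


def synthetic_mu_over_rho(Z: int, energies_kev: np.ndarray) -> np.ndarray:
    """Synthetic analytic mu/rho(E), cm^2/g.

    a/E^3 + b with a = 12 Z^3; for high-Z elements the photoelectric term
    is divided by the K-edge jump ratio below the K-edge energy, giving the
    discontinuity that distinguishes e.g. W from Al filtration in practice.
    """
    e = np.asarray(energies_kev, dtype=float)
    photo = SYNTHETIC_A_PER_Z3 * Z**3 / e**3
    ek = K_EDGE_KEV.get(Z)
    if ek is not None:
        photo = np.where(e < ek, photo / K_EDGE_JUMP, photo)
    return photo + SYNTHETIC_B


@dataclass
class AttenuationCurve:
    """mu/rho sampled at the bin centers of a grid, plus density.

    ``mu_linear`` is the derived linear attenuation coefficient in mm^-1.
    """

    material_id: str
    grid: EnergyGrid
    mu_over_rho: np.ndarray  # cm^2/g at grid.centers
    density: float  # g/cm^3

    def __post_init__(self) -> None:
        self.mu_over_rho = np.asarray(self.mu_over_rho, dtype=float)
        if self.mu_over_rho.shape != (self.grid.n_bins,):
            raise DataValidationError(
                f"curve length {self.mu_over_rho.size} != grid n_bins {self.grid.n_bins}"
            )
        if np.any(self.mu_over_rho < 0):
            raise DataValidationError(f"negative mu/rho in curve {self.material_id!r}")
        if not self.density > 0:
            raise DataValidationError(f"density must be > 0, got {self.density}")

    @property
    def mu_linear(self) -> np.ndarray:
        """Linear attenuation coefficient, mm^-1."""
        return self.mu_over_rho * self.density / 10.0


@dataclass
class CompoundSpec:
    """A compound: registry slot, composition by mass fraction, density."""

    name: str
    index: int  # registry slot 1-20
    composition: list[tuple[int, float]]  # (Z, mass fraction)
    density: float  # g/cm^3
    formula: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 20:
            raise DataValidationError(f"registry index {self.index} outside 1..20")
        total = sum(w for _, w in self.composition)
        if abs(total - 1.0) > 1e-9:
            raise DataValidationError(
                f"mass fractions of {self.name!r} sum to {total!r}, not 1"
            )


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def _fractions_from_formula(formula: str) -> list[tuple[int, float]]:
    """Mass fractions from a simple chemical formula (no parentheses)."""
    parsed = _FORMULA_TOKEN.findall(formula)
    if not parsed or "".join(s + n for s, n in parsed) != formula:
        raise DataValidationError(f"cannot parse formula {formula!r}")
    masses: dict[int, float] = {}
    for symbol, count in parsed:
        z = _SYMBOL_TO_Z.get(symbol.lower())
        if z is None:
            raise MaterialNotFoundError(f"unknown element {symbol!r} in {formula!r}")
        masses[z] = masses.get(z, 0.0) + ELEMENTS[z].atomic_weight * int(count or 1)
    total = sum(masses.values())
    return [(z, m / total) for z, m in sorted(masses.items())]


def _build_registry() -> list[CompoundSpec]:
    # (index, name, formula or explicit fractions, density g/cm^3)
    # GaAs 5.31 and Gd2O2S 7.44 g/cm^3 carry the corrected (previously
    # swapped) densities.
    rows: list[tuple[int, str, object, float]] = [
        (1, "Water", "H2O", 1.000),
        # Dry air near sea level, by mass
        (2, "Air", [(6, 0.000124), (7, 0.755267), (8, 0.231781), (18, 0.012828)], 1.205e-3),
        (3, "PMMA", "C5H8O2", 1.190),
        (4, "Polyethylene", "C2H4", 0.930),
        (5, "Polystyrene", "C8H8", 1.060),
        (6, "PTFE", "C2F4", 2.200),
        (7, "CsI", "CsI", 4.510),
        (8, "NaI", "NaI", 3.667),
        (9, "GaAs", "GaAs", 5.310),
        (10, "Gd2O2S", "Gd2O2S", 7.440),
        (11, "CaWO4", "CaWO4", 6.062),
        (12, "BGO", "Bi4Ge3O12", 7.130),
        (13, "CdTe", "CdTe", 5.850),
        (14, "SiO2", "SiO2", 2.320),
    ]
    registry = []
    for index, name, comp, density in rows:
        if isinstance(comp, str):
            fractions = _fractions_from_formula(comp)
            formula = comp
        else:
            total = sum(w for _, w in comp)
            fractions = [(z, w / total) for z, w in comp]
            formula = ""
        registry.append(
            CompoundSpec(name=name, index=index, composition=fractions,
                         density=density, formula=formula)
        )
    return registry


COMPOUND_REGISTRY: list[CompoundSpec] = _build_registry()


def _loglog_interp(src_e: np.ndarray, src_v: np.ndarray, query: np.ndarray) -> np.ndarray:
    """Piecewise log-log linear interpolation.

    Duplicated source energies (absorption-edge rows) produce a jump: a
    query between the edge and the next tabulated energy interpolates from
    the above-edge value only.
    """
    v = np.clip(src_v, 1e-300, None)
    out = np.exp(np.interp(np.log(query), np.log(src_e), np.log(v)))
    # a query exactly at a source energy returns the tabulated value
    # bit-for-bit (exp(log(x)) is off by an ulp otherwise)
    idx = np.searchsorted(src_e, query)
    exact = (idx < src_e.size) & (src_e[np.minimum(idx, src_e.size - 1)] == query)
    out[exact] = src_v[idx[exact]]
    return out


@dataclass
class _ElementTable:
    Z: int
    symbol: str
    density: float
    energies: np.ndarray  # keV, ascending (duplicates allowed at edges)
    mu_over_rho: np.ndarray  # cm^2/g


@dataclass
class MaterialLibrary:
    """Resolves element/compound identifiers to attenuation curves.

    Element data is a set of tabulated (energy, mu/rho) curves; compound
    curves are mass-fraction-weighted mixtures of element curves with the
    registry density.
    """

    elements: dict[int, _ElementTable]
    compounds: list[CompoundSpec] = field(default_factory=lambda: list(COMPOUND_REGISTRY))

    # -- element resolution ------------------------------------------------
    def resolve_element(self, material: int | str) -> int:
        if isinstance(material, str):
            key = material.strip().lower()
            for tab in self.elements.values():
                if tab.symbol.lower() == key:
                    return tab.Z
            raise MaterialNotFoundError(f"unknown element symbol {material!r}")
        z = int(material)
        if z not in self.elements:
            raise MaterialNotFoundError(f"element Z={z} not in attenuation dataset")
        return z

    def element_curve(self, material: int | str, grid: EnergyGrid = DEFAULT_GRID) -> AttenuationCurve:
        z = self.resolve_element(material)
        tab = self.elements[z]
        mu = _loglog_interp(tab.energies, tab.mu_over_rho, grid.centers)
        return AttenuationCurve(material_id=tab.symbol, grid=grid,
                                mu_over_rho=mu, density=tab.density)

    # -- compound resolution -----------------------------------------------
    def resolve_compound(self, material: int | str | CompoundSpec) -> CompoundSpec:
        if isinstance(material, CompoundSpec):
            return material
        if isinstance(material, str):
            for spec in self.compounds:
                if spec.name.lower() == material.strip().lower():
                    return spec
            raise MaterialNotFoundError(f"unknown compound name {material!r}")
        idx = int(material)
        for spec in self.compounds:
            if spec.index == idx:
                return spec
        raise MaterialNotFoundError(f"no compound at registry index {idx}")

    def compound_curve(self, material: int | str | CompoundSpec,
                       grid: EnergyGrid = DEFAULT_GRID) -> AttenuationCurve:
        spec = self.resolve_compound(material)
        total = sum(w for _, w in spec.composition)
        if abs(total - 1.0) > 1e-9:
            raise DataValidationError(
                f"mass fractions of {spec.name!r} sum to {total}, not 1"
            )
        mu = np.zeros(grid.n_bins)
        for z, w in spec.composition:
            mu += w * self.element_curve(z, grid).mu_over_rho
        return AttenuationCurve(material_id=spec.name, grid=grid,
                                mu_over_rho=mu, density=spec.density)

    def resolve_any_curve(self, material: int | str | CompoundSpec,
                          grid: EnergyGrid = DEFAULT_GRID) -> AttenuationCurve:
        """Element first, then compound (used by the CLI filter syntax)."""
        try:
            return self.element_curve(material, grid)
        except MaterialNotFoundError:
            return self.compound_curve(material, grid)


_DEFAULT_LIBRARY: MaterialLibrary | None = None


def default_library() -> MaterialLibrary:
    """The built-in synthetic material library.

    Curves are tabulated at the default grid's bin centers from the
    analytic form, so queries at those centers reproduce it exactly.
    """
    global _DEFAULT_LIBRARY
    if _DEFAULT_LIBRARY is None:
        centers = DEFAULT_GRID.centers
        tables = {}
        for e in ELEMENTS.values():
            energies = centers
            ek = K_EDGE_KEV.get(e.Z)
            if ek is not None and centers[0] < ek < centers[-1]:
                # duplicated-energy edge rows so interpolation never
                # crosses the discontinuity
                energies = np.sort(np.append(centers, [np.nextafter(ek, 0), ek]))
            tables[e.Z] = _ElementTable(
                Z=e.Z, symbol=e.symbol, density=e.density,
                energies=energies,
                mu_over_rho=synthetic_mu_over_rho(e.Z, energies),
            )
        _DEFAULT_LIBRARY = MaterialLibrary(elements=tables)
    return _DEFAULT_LIBRARY


def mu_rho_element(material: int | str, grid: EnergyGrid = DEFAULT_GRID,
                   library: MaterialLibrary | None = None) -> AttenuationCurve:
    """Attenuation curve for an element, by atomic number or symbol."""
    lib = library if library is not None else default_library()
    return lib.element_curve(material, grid)


def mu_rho_compound(material: int | str | CompoundSpec,
                    grid: EnergyGrid = DEFAULT_GRID,
                    library: MaterialLibrary | None = None) -> AttenuationCurve:
    """Attenuation curve for a compound, by registry index, name, or spec.

    The mixture rule is mu/rho(E) = sum_i w_i (mu/rho)_i(E) over mass
    fractions w_i; density comes from the registry entry or the spec.
    """
    lib = library if library is not None else default_library()
    return lib.compound_curve(material, grid)
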
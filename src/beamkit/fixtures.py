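"""Self-contained synthetic data for testing and demos.

Everything here is *synthetic*: a Kramers-shaped bremsstrahlung continuum
with Gaussian tungsten K-lines stands in for tabulated tungsten-anode
spectral models, analytic power-law curves stand in for measured
attenuation data, and a smooth analytic (mu_en/rho)_air closes the
dosimetry loop.  The fixture physics reproduces the *structure* of real
data (Duane-Hunt cutoff, characteristic lines above the K-edge, beam
hardening) but makes no claim of spectral fidelity; its role is to make
every operation in the toolkit testable with no downloads.  Fixture
artifacts pass the same validators as user-loaded data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .dosimetry import DoseConstants
from .errors import DataValidationError
from .grid import DEFAULT_GRID, EnergyGrid
from .materials import AttenuationCurve, ELEMENTS, default_library, synthetic_mu_over_rho
from .spectrum import (ScaleFactorTable, SpectralTable, Spectrum,
                       compute_scale_factors)

__all__ = [
    "FixtureConfig",
    "kramers_spectrum",
    "fixture_spectral_table",
    "fixture_attenuation",
    "fixture_dose_table",
    "synth_measurements",
    "bench_measurement_sets",
    "characterization_sets",
    "default_spectral_table",
    "legacy_reference_table",
    "default_scale_factors",
    "default_dose_constants",
]

# Tungsten K-alpha line energies (keV) and relative amplitudes.
TUNGSTEN_K_LINES = ((57.98, 1.0), (59.32, 0.55))
TUNGSTEN_K_EDGE_KEV = 69.5

DEFAULT_KV_NODES = tuple(range(20, 151, 10))
DEFAULT_MAS_STATIONS = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0)


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the synthetic spectrum generator.

    brems_coeff sets the Kramers continuum slope (photons/mm^2/mAs per
    keV of distance below the tube potential); line_yield_kev scales the
    total characteristic-line fluence per keV of overvoltage above the
    K-edge.  Everything is deterministic for a given config.
    """

    brems_coeff: float = 40.0  # photons/mm^2/mAs/keV
    lines: tuple[tuple[float, float], ...] = TUNGSTEN_K_LINES
    line_sigma_kev: float = 0.35
    line_yield_kev: float = 8.0
    k_edge_kev: float = TUNGSTEN_K_EDGE_KEV

    def line_component(self, kv: float, energies: np.ndarray) -> np.ndarray:
        """Characteristic-line fluence density (per keV) at ``energies``."""
        e = np.asarray(energies, dtype=float)
        out = np.zeros_like(e)
        if kv <= self.k_edge_kev:
            return out
        norm = 1.0 / (self.line_sigma_kev * math.sqrt(2.0 * math.pi))
        for e0, rel in self.lines:
            total = self.line_yield_kev * self.brems_coeff * (kv - self.k_edge_kev) * rel
            out += total * norm * np.exp(-0.5 * ((e - e0) / self.line_sigma_kev) ** 2)
        return out


DEFAULT_CONFIG = FixtureConfig()


def kramers_spectrum(kv: float, config: FixtureConfig = DEFAULT_CONFIG,
                     grid: EnergyGrid = DEFAULT_GRID) -> Spectrum:
    """Synthetic tube spectrum: Kramers continuum plus tungsten K-lines.

    The continuum is q(E) = brems_coeff * (kv - E_center) above zero and
    below the Duane-Hunt cutoff; Gaussian-profiled K-alpha lines (1 keV
    binned) appear only when the potential exceeds the K-edge.
    """
    if kv < 2.0:
        raise DataValidationError(f"kv={kv} below the 2 kV fixture minimum")
    centers = grid.centers
    q = config.brems_coeff * np.clip(kv - centers, 0.0, None)
    q += config.line_component(kv, centers)  # x 1 keV bin width
    q[grid.lower_edges >= kv] = 0.0
    return Spectrum(fluence=q, grid=grid, kv=kv, model_name="synthetic-kramers")


def fixture_spectral_table(kv_nodes=DEFAULT_KV_NODES,
                           config: FixtureConfig = DEFAULT_CONFIG,
                           grid: EnergyGrid = DEFAULT_GRID,
                           model_name: str = "synthetic-kramers") -> SpectralTable:
    """Spectral table whose node rows are Kramers fixture spectra."""
    nodes = np.asarray(list(kv_nodes), dtype=float)
    fluence = np.vstack([kramers_spectrum(kv, config, grid).fluence for kv in nodes])
    return SpectralTable(model_name=model_name, kv_nodes=nodes, fluence=fluence,
                         grid=grid, base_filtration="none (minimally filtered)")


def fixture_attenuation(materials, grid: EnergyGrid = DEFAULT_GRID
                        ) -> dict[str, AttenuationCurve]:
    """Analytic curves mu/rho(E) = 12 Z^3/E^3 + 0.18 cm^2/g (K-edge jump
    included for high-Z elements), sampled at the grid bin centers."""
    lib = default_library()
    out: dict[str, AttenuationCurve] = {}
    for material in materials:
        z = lib.resolve_element(material)
        elem = ELEMENTS[z]
        out[elem.symbol] = AttenuationCurve(
            material_id=elem.symbol, grid=grid,
            mu_over_rho=synthetic_mu_over_rho(z, grid.centers),
            density=elem.density,
        )
    return out


# Smooth analytic stand-in for the mass energy-absorption coefficient of
# air (cm^2/g): photoelectric-like E^-3 term plus a Compton-like floor.
AIR_MU_EN_A = 3.5e3  # keV^3 cm^2/g
AIR_MU_EN_B = 0.027  # cm^2/g


def fixture_dose_table(grid: EnergyGrid = DEFAULT_GRID) -> DoseConstants:
    """Synthetic (mu_en/rho)_air(E) = 3.5e3/E^3 + 0.027 cm^2/g."""
    return DoseConstants(grid=grid,
                         mu_en_over_rho_air=AIR_MU_EN_A / grid.centers**3 + AIR_MU_EN_B)


def synth_measurements(kv: float, t_al_true: float, t_w_true: float,
                       sdd_mm: float = 745.0, mas_list=DEFAULT_MAS_STATIONS,
                       noise_pct: float = 0.0, seed: int = 0,
                       config: FixtureConfig = DEFAULT_CONFIG,
                       reading_unit: str = "mR", added_filters=()):
    """Synthetic tube-output measurements for the filtration tuner.

    Readings are exposure (or air kerma) of the fixture spectrum hardened
    by the true (Al, W) thicknesses - plus any *known* added filters in
    the beam, which are recorded in the measurement set - scaled by mAs
    and by the inverse square of the source-detector distance, with
    centered multiplicative Gaussian noise of ``noise_pct`` percent
    (seeded, reproducible).
    """
    from .dosimetry import air_kerma, exposure
    from .filtration import beers_filter, FilterLayer
    from .tuner import MeasurementSet

    added = list(added_filters)
    spec = kramers_spectrum(kv, config)
    if added:
        spec = beers_filter(spec, added)
    spec = beers_filter(spec, [FilterLayer("Al", t_al_true), FilterLayer("W", t_w_true)])
    per_mas = exposure(spec) if reading_unit == "mR" else air_kerma(spec)
    mas = np.asarray(list(mas_list), dtype=float)
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, noise_pct / 100.0, size=mas.size) if noise_pct > 0 else np.zeros(mas.size)
    readings = per_mas * mas * (1000.0 / sdd_mm) ** 2 * (1.0 + eps)
    readings = np.clip(readings, 0.0, None)
    return MeasurementSet(kv=kv, sdd_mm=sdd_mm,
                          stations=list(zip(mas.tolist(), readings.tolist())),
                          reading_unit=reading_unit, added_filters=added)


def bench_measurement_sets(t_al_true: float, t_w_true: float,
                           kv_list=(60.0, 80.0, 100.0, 120.0, 140.0),
                           sdd_mm: float = 745.0, noise_pct: float = 0.0,
                           seed: int = 0, config: FixtureConfig = DEFAULT_CONFIG):
    """Open-beam measurement sets: 60-140 kV, six mAs stations each."""
    return [
        synth_measurements(kv, t_al_true, t_w_true, sdd_mm=sdd_mm,
                           noise_pct=noise_pct, seed=seed + i, config=config)
        for i, kv in enumerate(kv_list)
    ]


def characterization_sets(t_al_true: float, t_w_true: float,
                          noise_pct: float = 1.0, seed: int = 0,
                          sdd_mm: float = 745.0,
                          config: FixtureConfig = DEFAULT_CONFIG):
    """Full beam-characterization protocol for inherent-filtration recovery.

    A tube output reading at a single kV constrains one scalar, so open
    beams alone leave (t_Al, t_W) ill-conditioned; varying *known* added
    filtration - exactly how half-value layers are measured - separates
    the two.  The protocol: kv = 60..140 in 5 kV steps, each measured
    open and behind known Al (1, 2 mm) and Cu (0.1, 0.2 mm) filters, six
    mAs stations each.  The kv points sit on the default table nodes so
    the fitted forward model matches the generator exactly at zero noise.
    """
    from .filtration import FilterLayer

    conditions = ((), (FilterLayer("Al", 1.0),), (FilterLayer("Al", 2.0),),
                  (FilterLayer("Cu", 0.1),), (FilterLayer("Cu", 0.2),))
    sets = []
    i = 0
    for kv in range(60, 141, 10):
        for added in conditions:
            sets.append(synth_measurements(
                float(kv), t_al_true, t_w_true, sdd_mm=sdd_mm,
                noise_pct=noise_pct, seed=seed + i, config=config,
                added_filters=added))
            i += 1
    return sets


# ---------------------------------------------------------------------------
# Built-in default models (lazy, cached)

_DEFAULT_TABLE: SpectralTable | None = None
_LEGACY_TABLE: SpectralTable | None = None
_DEFAULT_SCALE: ScaleFactorTable | None = None
_DEFAULT_DOSE: dict[int, DoseConstants] = {}

# The legacy-role reference model: slightly hotter continuum, the two
# K-alpha lines merged into one (emulating coarser source resolution), and
# 1.6 mm Al already embodied in the table.
LEGACY_CONFIG = FixtureConfig(
    brems_coeff=42.0,
    lines=((59.5, 1.55),),
    line_sigma_kev=0.5,
)
LEGACY_INHERENT_AL_MM = 1.6


def default_spectral_table() -> SpectralTable:
    """The built-in minimally-filtered synthetic model (20-150 kV nodes)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = fixture_spectral_table()
    return _DEFAULT_TABLE


def legacy_reference_table() -> SpectralTable:
    """The built-in legacy-role reference model, inherently 1.6 mm Al filtered."""
    global _LEGACY_TABLE
    if _LEGACY_TABLE is None:
        from .filtration import FilterLayer, beers_filter

        raw = fixture_spectral_table(config=LEGACY_CONFIG,
                                     model_name="synthetic-legacy")
        filtered = np.vstack([
            beers_filter(Spectrum(row, grid=raw.grid), [FilterLayer("Al", LEGACY_INHERENT_AL_MM)]).fluence
            for row in raw.fluence
        ])
        _LEGACY_TABLE = SpectralTable(model_name="synthetic-legacy",
                                      kv_nodes=raw.kv_nodes, fluence=filtered,
                                      grid=raw.grid,
                                      base_filtration=f"{LEGACY_INHERENT_AL_MM} mm Al")
    return _LEGACY_TABLE


def default_scale_factors() -> ScaleFactorTable:
    """Factors normalizing the default model's output onto the legacy model's."""
    global _DEFAULT_SCALE
    if _DEFAULT_SCALE is None:
        primary = default_spectral_table()
        _DEFAULT_SCALE = compute_scale_factors(
            primary, legacy_reference_table(), primary.kv_nodes,
            a_added_al_mm=LEGACY_INHERENT_AL_MM,
        )
    return _DEFAULT_SCALE


def default_dose_constants(grid: EnergyGrid = DEFAULT_GRID) -> DoseConstants:
    """Cached synthetic dose table on the requested grid."""
    if grid.n_bins not in _DEFAULT_DOSE:
        _DEFAULT_DOSE[grid.n_bins] = fixture_dose_table(grid)
    return _DEFAULT_DOSE[grid.n_bins]


def write_demo_dataset(directory, seed: int = 0,
                       t_al_true: float = 0.5, t_w_true: float = 0.002,
                       noise_pct: float = 1.0) -> dict[str, str]:
    """Emit a complete demo dataset (tables + measurements) as CSV files.

    Everything goes through the standard writers so the loaders are
    exercised on read-back.  Returns a name -> path mapping.
    """
    from pathlib import Path

    from . import io as bio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    table = default_spectral_table()
    paths["spectral_table"] = str(directory / "spectral_table.csv")
    bio.write_spectral_table(paths["spectral_table"], table)

    paths["legacy_table"] = str(directory / "legacy_table.csv")
    bio.write_spectral_table(paths["legacy_table"], legacy_reference_table())

    att_dir = directory / "attenuation"
    curves = fixture_attenuation(["Al", "Cu", "W"])
    paths["attenuation_dir"] = str(att_dir)
    bio.write_attenuation_tables(att_dir, curves)

    paths["dose_table"] = str(directory / "dose_air.csv")
    bio.write_dose_table(paths["dose_table"], fixture_dose_table())

    paths["compounds"] = str(directory / "compounds.csv")
    bio.write_compound_registry(paths["compounds"])

    paths["scale_factors"] = str(directory / "scale_factors.csv")
    bio.write_scale_factors(paths["scale_factors"], default_scale_factors())

    for i, kv in enumerate((60.0, 80.0, 100.0, 120.0, 140.0)):
        ms = synth_measurements(kv, t_al_true, t_w_true, noise_pct=noise_pct,
                                seed=seed + i)
        key = f"measurements_{int(kv)}kv"
        paths[key] = str(directory / f"{key}.csv")
        bio.write_measurements(paths[key], ms)
    return paths
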
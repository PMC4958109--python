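"""CSV readers and writers for every toolkit artifact.

All formats are plain CSV with ``# key: value`` comment lines carrying
metadata above a mandatory header row.  Numeric output uses the shortest
decimal representation that reproduces the float64 exactly, so every
writer/reader pair is lossless and regression tests are bit-stable.

Schemas
-------
- Spectrum: columns ``bin_index, energy_center_keV, fluence_per_mm2_per_mAs``.
- Spectral table: columns ``bin_index, energy_center_keV, kv_<node>...``;
  one fluence column per tube-potential node, nodes ascending.
- Attenuation: one file per material with columns
  ``energy_keV, mu_over_rho_cm2_g``; element metadata (Z, symbol, density)
  in a sidecar ``elements.csv`` registry.
- Compound registry: ``index, name, formula, density_g_cm3, composition``
  with composition as ``Z:massfraction`` pairs joined by ``;``.
- Measurements: metadata kv/sdd_mm/unit plus added filters, then rows
  ``mAs, reading``.
- Scale factors: ``kv, factor``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .dosimetry import DoseConstants
from .errors import DataValidationError
from .grid import EnergyGrid
from .materials import (COMPOUND_REGISTRY, CompoundSpec, ELEMENTS,
                        MaterialLibrary, _ElementTable)
from .spectrum import ScaleFactorTable, SpectralTable, Spectrum
from .tuner import MeasurementSet
from .filtration import FilterLayer

__all__ = [
    "write_spectrum", "read_spectrum",
    "write_spectral_table", "load_spectral_table",
    "write_attenuation_tables", "load_attenuation_tables",
    "write_dose_table", "load_dose_table",
    "write_compound_registry", "load_compound_registry",
    "write_measurements", "load_measurements",
    "write_scale_factors", "load_scale_factors",
]

def _fmt(x: float) -> str:
    # shortest decimal that round-trips the float64 exactly, so every
    # writer/reader pair is lossless
    return repr(float(x))


def _read_meta_and_body(path) -> tuple[dict[str, str], pd.DataFrame]:
    meta: dict[str, str] = {}
    text = Path(path).read_text()
    body_lines = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, _, value = stripped.partition(":")
                meta[key.strip()] = value.strip()
        else:
            body_lines.append(line)
    try:
        body = pd.read_csv(_io.StringIO("\n".join(body_lines)),
                           float_precision="round_trip")
    except Exception as exc:  # surface parse failures as data errors
        raise DataValidationError(f"{path}: cannot parse CSV body: {exc}") from exc
    return meta, body


def _require_columns(body: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in body.columns]
    if missing:
        raise DataValidationError(f"{path}: missing required columns {missing}")


def _filters_to_str(layers) -> str:
    return ";".join(f"{layer.material}:{_fmt(layer.thickness_mm)}" for layer in layers)


def _filters_from_str(text: str) -> list[FilterLayer]:
    layers = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        material, _, thickness = token.rpartition(":")
        layers.append(FilterLayer(material, float(thickness)))
    return layers


# -- Spectrum ---------------------------------------------------------------

def write_spectrum(path, spectrum: Spectrum) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kv: {'' if spectrum.kv is None else _fmt(spectrum.kv)}\n")
        fh.write(f"# ripple_pct: {_fmt(spectrum.ripple_pct)}\n")
        fh.write(f"# model_name: {spectrum.model_name}\n")
        fh.write(f"# normalized: {int(spectrum.normalized)}\n")
        log = ";".join(f"{m}:{_fmt(t)}" for m, t in spectrum.filtration_log)
        fh.write(f"# filtration_log: {log}\n")
        fh.write("bin_index,energy_center_keV,fluence_per_mm2_per_mAs\n")
        for i, (e, q) in enumerate(zip(spectrum.grid.centers, spectrum.fluence), 1):
            fh.write(f"{i},{_fmt(e)},{_fmt(q)}\n")


def read_spectrum(path) -> Spectrum:
    meta, body = _read_meta_and_body(path)
    _require_columns(body, ["bin_index", "energy_center_keV",
                            "fluence_per_mm2_per_mAs"], path)
    grid = EnergyGrid(n_bins=len(body))
    layers = _filters_from_str(meta.get("filtration_log", ""))
    log = [(str(layer.material), layer.thickness_mm) for layer in layers]
    return Spectrum(
        fluence=body["fluence_per_mm2_per_mAs"].to_numpy(dtype=float),
        grid=grid,
        kv=float(meta["kv"]) if meta.get("kv") else None,
        ripple_pct=float(meta.get("ripple_pct", 0.0)),
        model_name=meta.get("model_name", ""),
        normalized=bool(int(meta.get("normalized", 0))),
        filtration_log=log,
    )


# -- Spectral table ---------------------------------------------------------

def write_spectral_table(path, table: SpectralTable) -> None:
    with open(path, "w") as fh:
        fh.write(f"# model_name: {table.model_name}\n")
        fh.write(f"# base_filtration: {table.base_filtration}\n")
        cols = ",".join(f"kv_{_fmt(kv)}" for kv in table.kv_nodes)
        fh.write(f"bin_index,energy_center_keV,{cols}\n")
        for i in range(table.grid.n_bins):
            row = ",".join(_fmt(v) for v in table.fluence[:, i])
            fh.write(f"{i + 1},{_fmt(table.grid.centers[i])},{row}\n")


NEGATIVE_CLAMP_TOL = 1e-9  # relative to the table maximum


def load_spectral_table(path) -> SpectralTable:
    """Load and validate a spectral table; Duane-Hunt violations are
    clamped to zero with a logged warning, negative fluence beyond the
    clamp tolerance is an error."""
    meta, body = _read_meta_and_body(path)
    _require_columns(body, ["bin_index", "energy_center_keV"], path)
    kv_cols = [c for c in body.columns if c.startswith("kv_")]
    if not kv_cols:
        raise DataValidationError(f"{path}: no kv_<node> fluence columns")
    nodes = []
    for c in kv_cols:
        try:
            nodes.append(float(c[3:]))
        except ValueError:
            raise DataValidationError(f"{path}: malformed node column {c!r}") from None
    for i in range(1, len(nodes)):
        if nodes[i] <= nodes[i - 1]:
            raise DataValidationError(
                f"{path}: kV nodes out of order at column {kv_cols[i]!r} "
                f"(node {nodes[i]} after {nodes[i - 1]})"
            )
    fluence = body[kv_cols].to_numpy(dtype=float).T
    floor = -NEGATIVE_CLAMP_TOL * max(fluence.max(), 1.0)
    if fluence.min() < floor:
        i_node, i_bin = np.unravel_index(int(fluence.argmin()), fluence.shape)
        raise DataValidationError(
            f"{path}: negative fluence {fluence.min():g} beyond clamp tolerance "
            f"at node {nodes[i_node]} kV, bin {i_bin + 1}"
        )
    fluence = np.clip(fluence, 0.0, None)
    return SpectralTable(
        model_name=meta.get("model_name", Path(path).stem),
        kv_nodes=np.asarray(nodes),
        fluence=fluence,
        grid=EnergyGrid(n_bins=len(body)),
        base_filtration=meta.get("base_filtration", ""),
    )


# -- Attenuation ------------------------------------------------------------

def write_attenuation_tables(directory, curves: dict) -> None:
    """Write per-material attenuation CSVs plus the elements.csv sidecar.

    ``curves`` maps a label to an AttenuationCurve (tabulated at its grid
    centers) or to an _ElementTable-like object with explicit energies.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "elements.csv", "w") as sidecar:
        sidecar.write("symbol,Z,name,density_g_cm3,file\n")
        for label, curve in curves.items():
            z = next((e.Z for e in ELEMENTS.values() if e.symbol == label), 0)
            name = ELEMENTS[z].name if z else label
            fname = f"{label}.csv"
            sidecar.write(f"{label},{z},{name},{_fmt(curve.density)},{fname}\n")
            energies = getattr(curve, "energies", None)
            if energies is None:
                energies = curve.grid.centers
            with open(directory / fname, "w") as fh:
                fh.write("energy_keV,mu_over_rho_cm2_g\n")
                for e, v in zip(energies, curve.mu_over_rho):
                    fh.write(f"{_fmt(e)},{_fmt(v)}\n")


def load_attenuation_tables(directory) -> MaterialLibrary:
    """Load a per-material attenuation directory into a MaterialLibrary."""
    directory = Path(directory)
    sidecar = pd.read_csv(directory / "elements.csv",
                          float_precision="round_trip")
    _require_columns(sidecar, ["symbol", "Z", "density_g_cm3", "file"],
                     directory / "elements.csv")
    tables = {}
    for _, row in sidecar.iterrows():
        fpath = directory / row["file"]
        body = pd.read_csv(fpath, float_precision="round_trip")
        _require_columns(body, ["energy_keV", "mu_over_rho_cm2_g"], fpath)
        energies = body["energy_keV"].to_numpy(dtype=float)
        values = body["mu_over_rho_cm2_g"].to_numpy(dtype=float)
        if np.any(np.diff(energies) < 0):
            bad = int(np.argmax(np.diff(energies) < 0)) + 2
            raise DataValidationError(f"{fpath}: energies decrease at line {bad + 1}")
        if np.any(values < 0):
            raise DataValidationError(f"{fpath}: negative mu/rho values")
        z = int(row["Z"])
        tables[z] = _ElementTable(Z=z, symbol=str(row["symbol"]),
                                  density=float(row["density_g_cm3"]),
                                  energies=energies, mu_over_rho=values)
    return MaterialLibrary(elements=tables)


# -- Dose table -------------------------------------------------------------

def write_dose_table(path, constants: DoseConstants) -> None:
    with open(path, "w") as fh:
        fh.write(f"# joule_per_kev: {_fmt(constants.joule_per_kev)}\n")
        fh.write(f"# mgy_per_roentgen: {_fmt(constants.mgy_per_roentgen)}\n")
        fh.write("energy_keV,mu_en_over_rho_cm2_g\n")
        for e, v in zip(constants.grid.centers, constants.mu_en_over_rho_air):
            fh.write(f"{_fmt(e)},{_fmt(v)}\n")


def load_dose_table(path) -> DoseConstants:
    meta, body = _read_meta_and_body(path)
    _require_columns(body, ["energy_keV", "mu_en_over_rho_cm2_g"], path)
    return DoseConstants(
        grid=EnergyGrid(n_bins=len(body)),
        mu_en_over_rho_air=body["mu_en_over_rho_cm2_g"].to_numpy(dtype=float),
        joule_per_kev=float(meta.get("joule_per_kev", 1.602176e-16)),
        mgy_per_roentgen=float(meta.get("mgy_per_roentgen", 8.764)),
    )


# -- Compound registry ------------------------------------------------------

def write_compound_registry(path, compounds: list[CompoundSpec] | None = None) -> None:
    compounds = compounds if compounds is not None else COMPOUND_REGISTRY
    with open(path, "w") as fh:
        fh.write("index,name,formula,density_g_cm3,composition\n")
        for spec in compounds:
            comp = ";".join(f"{z}:{w!r}" for z, w in spec.composition)
            fh.write(f"{spec.index},{spec.name},{spec.formula},"
                     f"{_fmt(spec.density)},{comp}\n")


def load_compound_registry(path) -> list[CompoundSpec]:
    body = pd.read_csv(path, float_precision="round_trip")
    _require_columns(body, ["index", "name", "density_g_cm3", "composition"], path)
    registry = []
    for _, row in body.iterrows():
        composition = []
        for token in str(row["composition"]).split(";"):
            z_str, _, w_str = token.partition(":")
            composition.append((int(z_str), float(w_str)))
        registry.append(CompoundSpec(
            name=str(row["name"]), index=int(row["index"]),
            composition=composition, density=float(row["density_g_cm3"]),
            formula="" if pd.isna(row.get("formula")) else str(row.get("formula", "")),
        ))
    return registry


# -- Measurements -----------------------------------------------------------

def write_measurements(path, ms: MeasurementSet) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kv: {_fmt(ms.kv)}\n")
        fh.write(f"# sdd_mm: {_fmt(ms.sdd_mm)}\n")
        fh.write(f"# unit: {ms.reading_unit}\n")
        fh.write(f"# added_filters: {_filters_to_str(ms.added_filters)}\n")
        fh.write("mAs,reading\n")
        for mas, reading in ms.stations:
            fh.write(f"{_fmt(mas)},{_fmt(reading)}\n")


def load_measurements(path) -> MeasurementSet:
    meta, body = _read_meta_and_body(path)
    _require_columns(body, ["mAs", "reading"], path)
    for key in ("kv", "sdd_mm", "unit"):
        if key not in meta:
            raise DataValidationError(f"{path}: missing metadata line '# {key}: ...'")
    return MeasurementSet(
        kv=float(meta["kv"]),
        sdd_mm=float(meta["sdd_mm"]),
        stations=[(float(m), float(r))
                  for m, r in zip(body["mAs"], body["reading"])],
        reading_unit=meta["unit"],
        added_filters=_filters_from_str(meta.get("added_filters", "")),
    )


# -- Scale factors ----------------------------------------------------------

def write_scale_factors(path, table: ScaleFactorTable) -> None:
    with open(path, "w") as fh:
        fh.write("kv,factor\n")
        for kv, factor in zip(table.kv, table.factor):
            fh.write(f"{_fmt(kv)},{_fmt(factor)}\n")


def load_scale_factors(path) -> ScaleFactorTable:
    body = pd.read_csv(path, comment="#", float_precision="round_trip")
    _require_columns(body, ["kv", "factor"], path)
    return ScaleFactorTable(kv=body["kv"].to_numpy(dtype=float),
                            factor=body["factor"].to_numpy(dtype=float))
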
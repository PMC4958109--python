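"""Fitting effective inherent (Al, W) filtration to measured tube output.

A real tube's inherent filtration (exit window, oil, anode self-filtration,
anode-angle effects) differs from what a tabulated spectral model assumes.
The tuner adjusts an effective Al thickness and an effective W thickness so
that the calculated tube output (mR/mAs or mGy/mAs at 100 cm) matches
dose-meter readings, minimizing a sum-of-squared-differences cost with the
Nelder-Mead simplex.  Negative thicknesses are admitted inside the search
(exp(-mu t) with t < 0 amplifies, letting the fit *remove* filtration the
model over-assumes).

Identifiability note: one measurement set at a single kV constrains only a
single scalar (the mAs-normalized output), so the zero-cost set in the
(t_Al, t_W) plane is a one-dimensional valley and the simplex returns the
valley point nearest the starting estimate.  Passing measurement sets at
several kV (the bench protocol) to :func:`tune` fits one (t_Al, t_W) pair
jointly across them, which pins down both parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .dosimetry import DoseConstants, air_kerma, exposure
from .errors import DataValidationError
from .filtration import FilterLayer, beers_filter, filter_with_curves
from .materials import MaterialLibrary, default_library
from .spectrum import SpectralTable, Spectrum, interpolate_fluence

logger = logging.getLogger(__name__)

__all__ = [
    "MeasurementSet",
    "TunerResult",
    "inverse_square_scale",
    "tuner_cost",
    "tune",
]

AL_Z = 13
W_Z = 74


@dataclass
class MeasurementSet:
    """Tube-output readings at one kV over several mAs stations."""

    kv: float
    sdd_mm: float
    stations: list[tuple[float, float]]  # (mAs, reading)
    reading_unit: str = "mR"  # "mR" (exposure) or "mGy" (air kerma)
    added_filters: list[FilterLayer] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.stations:
            raise DataValidationError("measurement set needs at least one station")
        if self.sdd_mm <= 0:
            raise DataValidationError(f"sdd_mm must be > 0, got {self.sdd_mm}")
        if self.reading_unit not in ("mR", "mGy"):
            raise DataValidationError(f"reading_unit must be mR or mGy, got {self.reading_unit!r}")
        for mas, reading in self.stations:
            if mas <= 0:
                raise DataValidationError(f"mAs must be > 0, got {mas}")
            if reading < 0:
                raise DataValidationError(f"reading must be >= 0, got {reading}")

    def normalized_readings(self) -> np.ndarray:
        """Per-mAs readings scaled to 100 cm by the inverse-square law."""
        return np.array([
            inverse_square_scale(reading / mas, self.sdd_mm)
            for mas, reading in self.stations
        ])


@dataclass
class TunerResult:
    """Fitted (Al, W) thicknesses with fit diagnostics.

    ``fitted`` is ((13, t_Al_mm), (74, t_W_mm)) - atomic number and
    thickness rows for Al and W.
    """

    fitted: tuple[tuple[int, float], tuple[int, float]]
    cost: float
    n_iterations: int
    converged: bool

    @property
    def t_al_mm(self) -> float:
        return self.fitted[0][1]

    @property
    def t_w_mm(self) -> float:
        return self.fitted[1][1]


def inverse_square_scale(reading: float, sdd_mm: float) -> float:
    """Scale a reading taken at ``sdd_mm`` to 100 cm: reading*(sdd/1000)^2."""
    return reading * (sdd_mm / 1000.0) ** 2


def _output_metric(spectrum: Spectrum, unit: str,
                   constants: DoseConstants | None) -> float:
    return exposure(spectrum, constants) if unit == "mR" else air_kerma(spectrum, constants)


def _prepare_base(kv: float, measurements: MeasurementSet,
                  table: SpectralTable | None, base_spectrum: Spectrum | None,
                  library: MaterialLibrary | None) -> Spectrum:
    if base_spectrum is None:
        if table is None:
            from . import fixtures
            table = fixtures.default_spectral_table()
        base_spectrum = Spectrum(interpolate_fluence(table, kv), grid=table.grid,
                                 kv=kv, model_name=table.model_name)
    if measurements.added_filters:
        lib = library if library is not None else default_library()
        base_spectrum = beers_filter(base_spectrum, measurements.added_filters,
                                     library=lib)
    return base_spectrum


def tuner_cost(t_al: float, t_w: float, base_spectrum: Spectrum,
               measurement_set: MeasurementSet,
               constants: DoseConstants | None = None,
               library: MaterialLibrary | None = None) -> float:
    """Sum of squared differences between calculated and measured output.

    The base spectrum (already carrying any known added filtration) is
    hardened by t_al mm of Al and t_w mm of W (either may be negative),
    its output metric computed per the measurement unit, and compared to
    each station's mAs-normalized, inverse-square-scaled reading.
    """
    lib = library if library is not None else default_library()
    al = lib.element_curve(AL_Z, base_spectrum.grid)
    w = lib.element_curve(W_Z, base_spectrum.grid)
    filtered = filter_with_curves(base_spectrum, [(al, t_al), (w, t_w)],
                                  allow_negative=True)
    calc = _output_metric(filtered, measurement_set.reading_unit, constants)
    residuals = calc - measurement_set.normalized_readings()
    return float(np.sum(residuals**2))


def _initial_simplex(x0: np.ndarray) -> np.ndarray:
    # step = 10% of the estimate with a 0.01 mm floor, per coordinate
    simplex = np.tile(x0, (3, 1))
    for i in range(2):
        simplex[i + 1, i] += max(0.1 * abs(x0[i]), 0.01)
    return simplex


def tune(kv: float | None, measurement_set: MeasurementSet | Sequence[MeasurementSet],
         estimate=((AL_Z, 0.5), (W_Z, 0.002)), *,
         table: SpectralTable | None = None,
         base_spectrum: Spectrum | None = None,
         constants: DoseConstants | None = None,
         library: MaterialLibrary | None = None,
         xatol: float = 1e-6, fatol: float = 1e-12,
         max_iterations: int = 2000) -> TunerResult:
    """Fit effective (Al, W) inherent filtration by Nelder-Mead simplex.

    ``measurement_set`` may be a single set (classic per-kV tuning; in the
    presence of the flat cost valley the minimum closest to the estimate
    is returned) or a sequence of sets at different kV, fitted jointly
    (identifiable).  ``estimate`` is ((13, t_Al0), (74, t_W0)); a plain
    (t_Al0, t_W0) pair is also accepted.

    Convergence: simplex size < ``xatol`` mm and cost change < ``fatol``;
    non-convergence within ``max_iterations`` returns the best point with
    ``converged=False``.
    """
    sets = [measurement_set] if isinstance(measurement_set, MeasurementSet) else list(measurement_set)
    if not sets:
        raise DataValidationError("no measurement sets supplied")

    est = np.asarray(estimate, dtype=float)
    if est.shape == (2, 2):
        if tuple(est[:, 0].astype(int)) != (AL_Z, W_Z):
            raise DataValidationError(
                "estimate rows must be ((13, t_Al), (74, t_W))"
            )
        x0 = est[:, 1].copy()
    elif est.shape == (2,):
        x0 = est.copy()
    else:
        raise DataValidationError("estimate must be 2x2 or a (t_Al, t_W) pair")

    lib = library if library is not None else default_library()
    bases = [
        _prepare_base(ms.kv if kv is None or len(sets) > 1 else kv, ms, table,
                      base_spectrum if len(sets) == 1 else None, lib)
        for ms in sets
    ]
    al_curves = [lib.element_curve(AL_Z, b.grid) for b in bases]
    w_curves = [lib.element_curve(W_Z, b.grid) for b in bases]
    targets = [ms.normalized_readings() for ms in sets]
    # joint fits weight residuals relative to each set's mean reading:
    # dose-meter noise is multiplicative, so this is the statistically
    # even-handed weighting across sets of very different output.  For a
    # single set it only scales the cost and leaves the argmin unchanged.
    weights = [1.0 / np.mean(y) if len(sets) > 1 and np.mean(y) > 0 else 1.0
               for y in targets]

    def cost(x: np.ndarray) -> float:
        total = 0.0
        # strongly negative thicknesses amplify beyond float range; the
        # resulting inf cost just steers the simplex away
        with np.errstate(over="ignore", invalid="ignore"):
            for base, al, w, ms, y, wt in zip(bases, al_curves, w_curves, sets,
                                              targets, weights):
                filtered = filter_with_curves(base, [(al, x[0]), (w, x[1])],
                                              allow_negative=True)
                calc = _output_metric(filtered, ms.reading_unit, constants)
                total += float(np.sum(((calc - y) * wt) ** 2))
        return total

    res = minimize(cost, x0, method="Nelder-Mead",
                   options={"xatol": xatol, "fatol": fatol,
                            "maxiter": max_iterations, "maxfev": 10 * max_iterations,
                            "initial_simplex": _initial_simplex(x0)})
    logger.info("tuner: %d iterations, cost %.3e, converged=%s",
                res.nit, res.fun, res.success)
    return TunerResult(
        fitted=((AL_Z, float(res.x[0])), (W_Z, float(res.x[1]))),
        cost=float(res.fun),
        n_iterations=int(res.nit),
        converged=bool(res.success),
    )


def tuning_report(result: TunerResult, measurement_sets: Sequence[MeasurementSet],
                  table: SpectralTable | None = None,
                  constants: DoseConstants | None = None,
                  library: MaterialLibrary | None = None):
    """Calculated-vs-measured table and pooled R^2 for a fitted result.

    Returns (rows, r_squared) where each row is (kv, measured_mean,
    calculated) in the measurement unit per mAs at 100 cm, and r_squared
    is the squared Pearson correlation pooled over all sets.
    """
    lib = library if library is not None else default_library()
    rows, measured, calculated = [], [], []
    for ms in measurement_sets:
        base = _prepare_base(ms.kv, ms, table, None, lib)
        al = lib.element_curve(AL_Z, base.grid)
        w = lib.element_curve(W_Z, base.grid)
        filtered = filter_with_curves(base, [(al, result.t_al_mm), (w, result.t_w_mm)],
                                      allow_negative=True)
        calc = _output_metric(filtered, ms.reading_unit, constants)
        y = float(np.mean(ms.normalized_readings()))
        rows.append((ms.kv, y, calc))
        measured.append(y)
        calculated.append(calc)
    if len(rows) >= 2 and np.ptp(measured) > 0 and np.ptp(calculated) > 0:
        r2 = float(np.corrcoef(measured, calculated)[0, 1] ** 2)
    else:
        r2 = float("nan")
    return rows, r2
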
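"""Spectrum generation from tabulated spectral models.

A spectral model is a table of per-bin photon fluence over a set of tube
potential nodes.  Spectra at intermediate potentials are obtained by
fitting a cubic spline *per energy bin* across the kV nodes (the same
scheme the cubic-spline tungsten-anode models use); generator voltage
ripple is modeled by averaging spectra over the waveform; added Al
filtration and an optional cross-model output normalization complete the
generation pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ConfigurationError, DataValidationError, OutOfRangeError
from .grid import DEFAULT_GRID, EnergyGrid

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "SpectralTable",
    "ScaleFactorTable",
    "SpectrumComparison",
    "interpolate_fluence",
    "apply_ripple",
    "generate_spectrum",
    "compute_scale_factors",
    "compare_spectra",
]

# Default added Al (mm) applied when normalization is on: matches the
# inherent filtration the legacy polynomial model embodies.
DEFAULT_INHERENT_AL_MM = 1.6


@dataclass
class Spectrum:
    """Photon fluence per 1 keV energy bin (photons/mm^2/mAs at 100 cm).

    ``filtration_log`` records every (material, thickness_mm) layer applied
    after generation so a spectrum is reproducible from its metadata.
    """

    fluence: np.ndarray
    grid: EnergyGrid = DEFAULT_GRID
    kv: float | None = None
    ripple_pct: float = 0.0
    model_name: str = ""
    normalized: bool = False
    filtration_log: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fluence = np.asarray(self.fluence, dtype=float)
        if self.fluence.shape != (self.grid.n_bins,):
            raise DataValidationError(
                f"fluence length {self.fluence.size} != grid n_bins {self.grid.n_bins}"
            )
        if np.any(self.fluence < 0):
            raise DataValidationError("negative fluence in spectrum")

    @property
    def total_fluence(self) -> float:
        return float(self.fluence.sum())

    def scaled(self, factor: float) -> "Spectrum":
        return replace(self, fluence=self.fluence * factor,
                       filtration_log=list(self.filtration_log))

    def copy(self) -> "Spectrum":
        return replace(self, fluence=self.fluence.copy(),
                       filtration_log=list(self.filtration_log))


@dataclass
class SpectralTable:
    """Tabulated fluence over (tube-potential node x energy bin).

    Invariants enforced on construction: kV nodes strictly ascending,
    fluence non-negative, and zero fluence above each node's Duane-Hunt
    limit (bins whose lower edge >= kV); violations of the last are clamped
    with a logged warning.
    """

    model_name: str
    kv_nodes: np.ndarray
    fluence: np.ndarray  # shape (n_nodes, n_bins)
    grid: EnergyGrid = DEFAULT_GRID
    base_filtration: str = ""

    def __post_init__(self) -> None:
        self.kv_nodes = np.asarray(self.kv_nodes, dtype=float)
        self.fluence = np.asarray(self.fluence, dtype=float)
        if self.kv_nodes.ndim != 1 or self.kv_nodes.size < 2:
            raise DataValidationError("need at least two kV nodes")
        diffs = np.diff(self.kv_nodes)
        if np.any(diffs <= 0):
            bad = int(np.argmax(diffs <= 0)) + 1
            raise DataValidationError(
                f"kV nodes not strictly ascending at node {bad} "
                f"(kv={self.kv_nodes[bad]})"
            )
        if self.fluence.shape != (self.kv_nodes.size, self.grid.n_bins):
            raise DataValidationError(
                f"fluence shape {self.fluence.shape} != "
                f"({self.kv_nodes.size}, {self.grid.n_bins})"
            )
        if np.any(self.fluence < 0):
            raise DataValidationError("negative fluence in spectral table")
        # Duane-Hunt limit: no photons at or above the tube potential.
        mask = self.grid.lower_edges[None, :] >= self.kv_nodes[:, None]
        if np.any(self.fluence[mask] != 0):
            logger.warning(
                "spectral table %r: clamped %d bins above the Duane-Hunt "
                "limit to zero", self.model_name, int(np.count_nonzero(self.fluence[mask])),
            )
            self.fluence = np.where(mask, 0.0, self.fluence)

    @property
    def kv_min(self) -> float:
        return float(self.kv_nodes[0])

    @property
    def kv_max(self) -> float:
        return float(self.kv_nodes[-1])


@dataclass
class ScaleFactorTable:
    """Per-kV multiplicative factor mapping one model's output onto another's."""

    kv: np.ndarray
    factor: np.ndarray

    def __post_init__(self) -> None:
        self.kv = np.asarray(self.kv, dtype=float)
        self.factor = np.asarray(self.factor, dtype=float)
        if self.kv.shape != self.factor.shape or self.kv.ndim != 1:
            raise DataValidationError("kv and factor must be 1-D and equal length")
        if np.any(np.diff(self.kv) <= 0):
            raise DataValidationError("scale-factor kV values must be ascending")
        if np.any(self.factor <= 0):
            raise DataValidationError("scale factors must be positive")

    def __call__(self, kv: float) -> float:
        """Factor at ``kv``, linearly interpolated between stored kV."""
        if kv < self.kv[0] or kv > self.kv[-1]:
            raise OutOfRangeError(
                f"kv={kv} outside scale-factor range [{self.kv[0]}, {self.kv[-1]}]"
            )
        return float(np.interp(kv, self.kv, self.factor))


def _spline(table: SpectralTable) -> CubicSpline:
    # not-a-knot boundary: reproduces tables generated by a single cubic
    # polynomial of kV exactly, and is the standard default.
    return CubicSpline(table.kv_nodes, table.fluence, axis=0, bc_type="not-a-knot")


def interpolate_fluence(table: SpectralTable, kv: float) -> np.ndarray:
    """Per-bin fluence at tube potential ``kv``.

    A cubic spline across the kV nodes is fitted independently per energy
    bin; the result is clamped at zero from below (spline ringing near the
    Duane-Hunt cutoff).  Queries outside the node range raise
    :class:`OutOfRangeError` - there is no silent extrapolation.
    """
    if not table.kv_min <= kv <= table.kv_max:
        raise OutOfRangeError(
            f"kv={kv} outside table range [{table.kv_min}, {table.kv_max}]"
        )
    exact = np.nonzero(table.kv_nodes == kv)[0]
    if exact.size:
        return table.fluence[exact[0]].copy()
    return np.clip(_spline(table)(kv), 0.0, None)


def apply_ripple(table: SpectralTable, kv: float, ripple_pct: float,
                 n_samples: int = 100) -> np.ndarray:
    """Ripple-averaged fluence at peak potential ``kv``.

    The generator waveform is modeled as a sawtooth sweeping the potential
    from kv*(1 - ripple_pct/100) up to kv; the output is the unweighted
    mean spectrum over ``n_samples`` uniform phase samples (endpoints
    included).  ripple_pct = 0 reduces to plain interpolation.
    """
    if not 0 <= ripple_pct < 100:
        raise DataValidationError(f"ripple_pct must be in [0, 100), got {ripple_pct}")
    if ripple_pct == 0:
        return interpolate_fluence(table, kv)
    kv_lo = kv * (1.0 - ripple_pct / 100.0)
    if kv_lo < table.kv_min:
        raise OutOfRangeError(
            f"ripple trough {kv_lo:.3f} kV below table minimum {table.kv_min}"
        )
    samples = np.linspace(kv_lo, kv, n_samples)
    out = np.zeros(table.grid.n_bins)
    for v in samples:
        out += interpolate_fluence(table, v)
    return out / n_samples


def generate_spectrum(kv: float, added_al_mm: float | None = None,
                      ripple_pct: float = 0.0, *,
                      table: SpectralTable | None = None,
                      normalize: bool = True,
                      scale_factors: ScaleFactorTable | None = None,
                      library=None, n_ripple_samples: int = 100) -> Spectrum:
    """Generate a spectrum: kV interpolation, ripple, added Al, normalization.

    With no arguments beyond ``kv`` this uses the default (synthetic) model
    with 1.6 mm added Al inherent filtration, 0 % ripple, and output
    normalization onto the built-in legacy reference model.  When
    ``normalize`` is off and no Al is requested explicitly, no filtration
    is added.

    Parameters
    ----------
    added_al_mm : float, optional
        Added Al filtration in mm.  Default: 1.6 when ``normalize`` is on
        (the inherent filtration the normalization target embodies), else 0.
    scale_factors : ScaleFactorTable, optional
        Required when ``normalize`` is on and ``table`` is user-supplied;
        for the default model a built-in table is computed lazily.
    """
    from . import fixtures  # default model lives there; avoid import cycle
    from .filtration import FilterLayer, beers_filter

    if table is None:
        table = fixtures.default_spectral_table()
        if normalize and scale_factors is None:
            scale_factors = fixtures.default_scale_factors()
    if normalize and scale_factors is None:
        raise ConfigurationError(
            "normalize requested but no scale-factor table configured "
            "(pass scale_factors= or use normalize=False)"
        )
    if added_al_mm is None:
        added_al_mm = DEFAULT_INHERENT_AL_MM if normalize else 0.0
    if added_al_mm < 0:
        raise DataValidationError(f"added_al_mm must be >= 0, got {added_al_mm}")

    fluence = apply_ripple(table, kv, ripple_pct, n_samples=n_ripple_samples)
    spec = Spectrum(fluence=fluence, grid=table.grid, kv=kv,
                    ripple_pct=ripple_pct, model_name=table.model_name,
                    normalized=False)
    if added_al_mm > 0:
        spec = beers_filter(spec, [FilterLayer("Al", added_al_mm)], library=library)
    if normalize:
        spec = spec.scaled(scale_factors(kv))
        spec.normalized = True
    return spec


def compute_scale_factors(model_a: SpectralTable, model_b: SpectralTable,
                          kv_list, a_added_al_mm: float = DEFAULT_INHERENT_AL_MM,
                          *, dose_constants=None, library=None) -> ScaleFactorTable:
    """Per-kV factors normalizing model A's tube output onto model B's.

    s(kv) = air_kerma(B at kv) / air_kerma(A at kv filtered by
    ``a_added_al_mm`` of Al), so that a model-A spectrum generated with that
    added filtration and multiplied by s(kv) reproduces model B's
    mGy/mAs at 100 cm exactly at every listed kv.
    """
    from .dosimetry import air_kerma
    from .filtration import FilterLayer, beers_filter

    kv_arr = np.asarray(list(kv_list), dtype=float)
    factors = np.empty_like(kv_arr)
    for i, kv in enumerate(kv_arr):
        spec_a = Spectrum(interpolate_fluence(model_a, kv), grid=model_a.grid, kv=kv)
        if a_added_al_mm > 0:
            spec_a = beers_filter(spec_a, [FilterLayer("Al", a_added_al_mm)],
                                  library=library)
        spec_b = Spectrum(interpolate_fluence(model_b, kv), grid=model_b.grid, kv=kv)
        kerma_a = air_kerma(spec_a, constants=dose_constants)
        kerma_b = air_kerma(spec_b, constants=dose_constants)
        if kerma_a <= 0 or kerma_b <= 0:
            raise DataValidationError(
                f"zero air kerma at kv={kv} (a={kerma_a}, b={kerma_b})"
            )
        factors[i] = kerma_b / kerma_a
    return ScaleFactorTable(kv=kv_arr, factor=factors)


@dataclass
class SpectrumComparison:
    """Pooled per-bin percent differences between two models."""

    percent_diff: np.ndarray  # pooled over (kv, bin), reference = model_b
    median_percent_diff: float
    r_squared: dict[float, float]  # per-kv squared Pearson correlation
    n_zero_excluded: int


def compare_spectra(model_a, model_b, kv_list, bin_range: tuple[int, int] | None = None,
                    ) -> SpectrumComparison:
    """Bin-wise percent difference and per-kV correlation of two models.

    ``model_a``/``model_b`` are SpectralTables (interpolated directly) or
    callables kv -> Spectrum.  Percent difference per bin is
    100*(a - b)/b with model B as the reference; bins where b = 0 are
    excluded from the pool and counted.  ``bin_range`` is an inclusive
    (lo, hi) pair of 1-based bin indices.
    """

    def spectrum_of(model, kv: float) -> np.ndarray:
        if isinstance(model, SpectralTable):
            return interpolate_fluence(model, kv)
        out = model(kv)
        return out.fluence if isinstance(out, Spectrum) else np.asarray(out, float)

    pooled: list[np.ndarray] = []
    r2: dict[float, float] = {}
    n_excluded = 0
    for kv in kv_list:
        a = spectrum_of(model_a, kv)
        b = spectrum_of(model_b, kv)
        if bin_range is not None:
            lo, hi = bin_range
            a, b = a[lo - 1:hi], b[lo - 1:hi]
        nonzero = b != 0
        n_excluded += int(np.count_nonzero(~nonzero))
        pooled.append(100.0 * (a[nonzero] - b[nonzero]) / b[nonzero])
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            r2[float(kv)] = 1.0 if np.allclose(a, b) else 0.0
        else:
            r2[float(kv)] = float(np.corrcoef(a, b)[0, 1] ** 2)
    diffs = np.concatenate(pooled) if pooled else np.array([])
    if diffs.size == 0:
        raise DataValidationError("empty comparison pool after zero-bin exclusion")
    return SpectrumComparison(
        percent_diff=diffs,
        median_percent_diff=float(np.median(diffs)),
        r_squared=r2,
        n_zero_excluded=n_excluded,
    )
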
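"""Beer-Lambert filtration of spectra through stacks of materials.

Narrow-beam exponential attenuation only: out(E) = in(E) * exp(-sum_i
mu_i(E) * t_i) with mu in mm^-1 and thickness in mm.  No scatter, buildup,
or geometry.  Negative thicknesses (which *amplify*) are rejected here;
the filtration tuner admits them internally during cost evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Union

import numpy as np

from .errors import DataValidationError
from .materials import AttenuationCurve, CompoundSpec, MaterialLibrary, default_library
from .spectrum import Spectrum

__all__ = ["FilterLayer", "beers_filter", "beers_filter_compounds"]

MaterialRef = Union[int, str, CompoundSpec]


@dataclass(frozen=True)
class FilterLayer:
    """One filter: a material reference and a thickness in mm."""

    material: MaterialRef
    thickness_mm: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.thickness_mm):
            raise DataValidationError(f"non-finite thickness {self.thickness_mm}")


def _apply(spectrum: Spectrum, curves_and_thicknesses, labels,
           allow_negative: bool) -> Spectrum:
    pairs = list(curves_and_thicknesses)
    for _, t in pairs:
        if t < 0 and not allow_negative:
            raise DataValidationError(f"negative thickness {t} mm not allowed here")
    # canonical summation order: layer stacks commute bit-for-bit
    order = sorted(range(len(pairs)),
                   key=lambda i: (str(pairs[i][0].material_id), pairs[i][1]))
    exponent = np.zeros(spectrum.grid.n_bins)
    for i in order:
        curve, t = pairs[i]
        exponent += curve.mu_linear * t
    # negative thickness can amplify beyond float range; saturate rather
    # than overflow so tuner cost evaluations stay finite-ordered
    with np.errstate(over="ignore", invalid="ignore"):
        attenuated = spectrum.fluence * np.exp(-exponent)
    return replace(
        spectrum,
        fluence=np.nan_to_num(attenuated, nan=0.0, posinf=np.finfo(float).max),
        filtration_log=list(spectrum.filtration_log) + labels,
    )


def beers_filter(spectrum: Spectrum, layers: Iterable[FilterLayer],
                 library: MaterialLibrary | None = None,
                 allow_negative: bool = False) -> Spectrum:
    """Filter a spectrum through elemental layers (Z or chemical symbol)."""
    lib = library if library is not None else default_library()
    pairs, labels = [], []
    for layer in layers:
        curve = lib.element_curve(layer.material, spectrum.grid)
        pairs.append((curve, layer.thickness_mm))
        labels.append((curve.material_id, float(layer.thickness_mm)))
    return _apply(spectrum, pairs, labels, allow_negative)


def beers_filter_compounds(spectrum: Spectrum, layers: Iterable[FilterLayer],
                           library: MaterialLibrary | None = None,
                           allow_negative: bool = False) -> Spectrum:
    """Filter through compound layers (registry index, name, or spec)."""
    lib = library if library is not None else default_library()
    pairs, labels = [], []
    for layer in layers:
        curve = lib.compound_curve(layer.material, spectrum.grid)
        pairs.append((curve, layer.thickness_mm))
        labels.append((curve.material_id, float(layer.thickness_mm)))
    return _apply(spectrum, pairs, labels, allow_negative)


def filter_with_curves(spectrum: Spectrum,
                       curves_and_thicknesses: Iterable[tuple[AttenuationCurve, float]],
                       allow_negative: bool = False) -> Spectrum:
    """Filter using pre-resolved curves (fast path for the tuner's inner loop)."""
    pairs = list(curves_and_thicknesses)
    labels = [(c.material_id, float(t)) for c, t in pairs]
    return _apply(spectrum, pairs, labels, allow_negative)
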
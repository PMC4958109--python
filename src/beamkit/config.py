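"""Run configuration and x-ray tube presets.

A config file is a small YAML document selecting data files, the default
spectral model, dosimetry constants, and named tube presets; command-line
flags override config values.  A tube preset bundles the inherent
filtration layers and generator ripple of a particular tube so repeated
runs are reproducible from one file.

Example config::

    model: path/to/spectral_table.csv      # or "fixture"
    scale_factors: path/to/scale.csv       # or "default"
    attenuation_dir: path/to/attenuation   # or "fixture"
    dose_table: path/to/dose_air.csv       # or "fixture"
    presets:
      lab-tube:
        filters: [["Al", 2.0], ["Cu", 0.2]]
        ripple_pct: 5.0
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import DataValidationError

__all__ = ["TubePreset", "RunConfig", "load_config", "BUILTIN_PRESETS"]


@dataclass(frozen=True)
class TubePreset:
    """Named bundle of inherent filtration and ripple for one tube."""

    name: str
    filters: tuple[tuple[str, float], ...] = ()
    ripple_pct: float = 0.0
    model: str = "fixture"


BUILTIN_PRESETS: dict[str, TubePreset] = {
    p.name: p for p in (
        TubePreset(name="minimal"),
        TubePreset(name="standard", filters=(("Al", 1.6),)),
        TubePreset(name="heavy", filters=(("Al", 2.5), ("Cu", 0.2)), ripple_pct=5.0),
    )
}


@dataclass
class RunConfig:
    model: str = "fixture"
    scale_factors: str = "default"
    attenuation_dir: str = "fixture"
    dose_table: str = "fixture"
    presets: dict[str, TubePreset] = field(default_factory=dict)
    source_text: str = ""

    @property
    def config_hash(self) -> str:
        """Short digest of the config content, logged with every run."""
        return hashlib.sha256(self.source_text.encode()).hexdigest()[:12]

    def preset(self, name: str) -> TubePreset:
        if name in self.presets:
            return self.presets[name]
        if name in BUILTIN_PRESETS:
            return BUILTIN_PRESETS[name]
        raise DataValidationError(f"unknown tube preset {name!r}")


def load_config(path=None) -> RunConfig:
    """Load a YAML config file; with no path, return defaults."""
    if path is None:
        return RunConfig()
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise DataValidationError(f"{path}: config must be a mapping")
    presets = {}
    for name, spec in (raw.get("presets") or {}).items():
        filters = tuple((str(m), float(t)) for m, t in (spec.get("filters") or []))
        presets[name] = TubePreset(name=name, filters=filters,
                                   ripple_pct=float(spec.get("ripple_pct", 0.0)),
                                   model=str(spec.get("model", "fixture")))
    return RunConfig(
        model=str(raw.get("model", "fixture")),
        scale_factors=str(raw.get("scale_factors", "default")),
        attenuation_dir=str(raw.get("attenuation_dir", "fixture")),
        dose_table=str(raw.get("dose_table", "fixture")),
        presets=presets,
        source_text=text,
    )
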
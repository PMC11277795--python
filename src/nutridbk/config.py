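"""Pipeline configuration: every tunable default, loadable from YAML.

The effective configuration is echoed into every output directory so a
compiled databank or recipe table can always be traced back to the
exact conversion factors, measure equivalents and policies that
produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

from .fct import DEFAULT_FILL_FIELDS, DEFAULT_SOURCE_PRIORITY, Source
from .nutrients import DEFAULT_ENERGY_RTOL, EnergyConversion, NullPolicy
from .recipes import MeasureConversionTable

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    source_priority: tuple[Source, ...] = DEFAULT_SOURCE_PRIORITY
    energy: EnergyConversion = dc_field(default_factory=EnergyConversion)
    energy_rtol: float = DEFAULT_ENERGY_RTOL
    measures: MeasureConversionTable = dc_field(default_factory=MeasureConversionTable)
    null_policy: NullPolicy = NullPolicy.ZERO_FLAG
    on_unmatched: str = "error"  # "error" | "exclude"
    fill_fields: tuple[str, ...] = tuple(sorted(DEFAULT_FILL_FIELDS))
    match_key: str = "food_code"

    def __post_init__(self) -> None:
        if self.on_unmatched not in ("error", "exclude"):
            raise ValueError(f"on_unmatched must be 'error' or 'exclude', got {self.on_unmatched!r}")
        if self.match_key not in ("food_code", "normalized_name"):
            raise ValueError(f"unknown match_key {self.match_key!r}")
        if len(set(self.source_priority)) != len(self.source_priority):
            raise ValueError("source_priority contains duplicates")

    # -- serialisation --------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return {
            "source_priority": [s.value for s in self.source_priority],
            "energy": {
                "kj_per_kcal": self.energy.kj_per_kcal,
                "kcal_per_kj": self.energy.kcal_per_kj,
            },
            "energy_rtol": self.energy_rtol,
            "measures": {
                "volume_ml": dict(self.measures.volume_ml),
                "mass_g": dict(self.measures.mass_g),
                "default_density_g_per_ml": self.measures.default_density_g_per_ml,
                "density_g_per_ml": dict(self.measures.density_g_per_ml),
            },
            "null_policy": self.null_policy.value,
            "on_unmatched": self.on_unmatched,
            "fill_fields": list(self.fill_fields),
            "match_key": self.match_key,
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PipelineConfig":
        base = cls()
        m = d.get("measures", {})
        e = d.get("energy", {})
        return cls(
            source_priority=tuple(Source(s) for s in d.get("source_priority", [s.value for s in base.source_priority])),
            energy=EnergyConversion(
                kj_per_kcal=float(e.get("kj_per_kcal", base.energy.kj_per_kcal)),
                kcal_per_kj=float(e.get("kcal_per_kj", base.energy.kcal_per_kj)),
            ),
            energy_rtol=float(d.get("energy_rtol", base.energy_rtol)),
            measures=MeasureConversionTable(
                volume_ml={k: float(v) for k, v in m.get("volume_ml", dict(base.measures.volume_ml)).items()},
                mass_g={k: float(v) for k, v in m.get("mass_g", dict(base.measures.mass_g)).items()},
                default_density_g_per_ml=float(
                    m.get("default_density_g_per_ml", base.measures.default_density_g_per_ml)
                ),
                density_g_per_ml={k: float(v) for k, v in m.get("density_g_per_ml", {}).items()},
            ),
            null_policy=NullPolicy(d.get("null_policy", base.null_policy.value)),
            on_unmatched=d.get("on_unmatched", base.on_unmatched),
            fill_fields=tuple(d.get("fill_fields", list(base.fill_fields))),
            match_key=d.get("match_key", base.match_key),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def with_overrides(self, **changes: Any) -> "PipelineConfig":
        return replace(self, **changes)
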
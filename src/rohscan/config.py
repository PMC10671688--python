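"""YAML pipeline configuration with strict schema validation.

The file mirrors the per-stage parameter objects section by section::

    qc:       {autosome_max: 26, min_maf: 0.05, ...}
    roh:      {window_snps: 15, min_length_kb: 1000, ...}
    classes:  {edges_mb: [1, 2, 4, 8, 16]}
    islands:  {top_pct: 1.0, max_island_gap_kb: 1000, min_island_snps: 3}
    sim:      {n_individuals: 100, seed: 0, ...}
    io:       {ped: ..., map: ..., genes: ..., gene_dialect: BED, out_dir: ...}
    populations: {FAM1: POP1, ...}   # family_id -> cohort label

Unknown keys raise a schema error naming the key; CLI flags override the
file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .detect import ROHParams
from .qc import QCConfig
from .simulate import PlantedIsland, QCSpike, SimConfig
from .stats import LengthClassScheme


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass(frozen=True)
class IslandParams:
    top_pct: float = 1.0
    max_island_gap_kb: float = 1000.0
    min_island_snps: int = 3


@dataclass(frozen=True)
class IOConfig:
    ped: str | None = None
    map: str | None = None
    genes: str | None = None
    gene_dialect: str = "BED"
    out_dir: str = "results"


@dataclass
class PipelineConfig:
    qc: QCConfig = field(default_factory=QCConfig)
    roh: ROHParams = field(default_factory=ROHParams)
    classes: LengthClassScheme = field(default_factory=LengthClassScheme)
    islands: IslandParams = field(default_factory=IslandParams)
    sim: SimConfig = field(default_factory=SimConfig)
    io: IOConfig = field(default_factory=IOConfig)
    populations: dict[str, str] = field(default_factory=dict)

    def population_label(self, family_id: str) -> str:
        return self.populations.get(family_id, family_id)

    def echo(self) -> dict[str, Any]:
        """Plain-dict dump of every parameter actually in force."""
        out: dict[str, Any] = {}
        for name in ("qc", "roh", "classes", "islands", "sim", "io"):
            out[name] = dataclasses.asdict(getattr(self, name))
        out["populations"] = dict(self.populations)
        return out


_TUPLE_FIELDS = {"edges_mb", "chromosomes", "planted_islands", "populations",
                 "freq_range"}


def _build_section(cls: type, data: Mapping[str, Any], section: str) -> Any:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in config section {section!r}"
        )
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key == "planted_islands":
            value = tuple(
                PlantedIsland(**v) if isinstance(v, Mapping) else PlantedIsland(*v)
                for v in value
            )
        elif key == "qc_spike" and isinstance(value, Mapping):
            value = _build_section(QCSpike, value, f"{section}.qc_spike")
        elif key in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
            value = tuple(tuple(v) if isinstance(v, (list, tuple)) else v
                          for v in value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"config section {section!r}: {exc}") from exc


_SECTIONS: dict[str, type] = {
    "qc": QCConfig,
    "roh": ROHParams,
    "classes": LengthClassScheme,
    "islands": IslandParams,
    "sim": SimConfig,
    "io": IOConfig,
}


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Mapping[str, Any]] | None = None
                ) -> PipelineConfig:
    """Load a config file (all sections optional) and apply overrides.

    ``overrides`` maps section name to {field: value}, taking precedence
    over the file (this is how CLI flags are merged in).
    """
    raw: dict[str, Any] = {}
    if path is not None:
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - set(_SECTIONS) - {"populations"}
    if unknown:
        raise ConfigError(f"unknown top-level config key(s) {sorted(unknown)}")

    merged: dict[str, dict[str, Any]] = {
        name: dict(raw.get(name) or {}) for name in _SECTIONS
    }
    if overrides:
        for section, values in overrides.items():
            merged.setdefault(section, {}).update(
                {k: v for k, v in values.items() if v is not None}
            )

    cfg = PipelineConfig(
        **{name: _build_section(cls, merged[name], name)
           for name, cls in _SECTIONS.items()}
    )
    populations = raw.get("populations") or {}
    if not isinstance(populations, Mapping):
        raise ConfigError("config section 'populations' must be a mapping")
    cfg.populations = {str(k): str(v) for k, v in populations.items()}
    return cfg


__all__ = ["ConfigError", "IslandParams", "IOConfig", "PipelineConfig",
           "load_config"]
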
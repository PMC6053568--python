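"""Run configuration: YAML files mapped onto typed sections with defaults.

Every parameter has a default; unknown keys are rejected so that a typo in a
config file fails loudly instead of silently using a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dynamics import SimulationParams
from .synthetic import SyntheticConfig

__all__ = [
    "HabitatConfig",
    "AnalysisConfig",
    "NullModelConfig",
    "OutputConfig",
    "RunConfig",
    "load_config",
    "config_to_dict",
]


@dataclass
class HabitatConfig:
    levels: int = 4
    spacings: tuple[float, ...] | None = None  # metres per level; None = defaults


@dataclass
class AnalysisConfig:
    scales: tuple[int, ...] | None = None  # None = all layout scales except the top
    include_top_scale: bool = False


@dataclass
class NullModelConfig:
    n_iter: int = 10_000
    mode: str = "cell"  # 'cell' or 'series' donor redraw
    seed: int | None = None


@dataclass
class OutputConfig:
    directory: str = "."


@dataclass
class RunConfig:
    habitat: HabitatConfig = field(default_factory=HabitatConfig)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    nullmodel: NullModelConfig = field(default_factory=NullModelConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    output: OutputConfig = field(default_factory=OutputConfig)


_SECTIONS = {
    "habitat": HabitatConfig,
    "simulation": SimulationParams,
    "analysis": AnalysisConfig,
    "nullmodel": NullModelConfig,
    "synthetic": SyntheticConfig,
    "output": OutputConfig,
}

_TUPLE_FIELDS = {"spacings", "scales", "record_times"}


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown keys in config section '{section}': {sorted(unknown)}; "
            f"valid keys: {sorted(known)}"
        )
    kwargs = {
        k: tuple(v) if k in _TUPLE_FIELDS and v is not None else v
        for k, v in data.items()
    }
    return cls(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML config file; missing sections/keys fall back to defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping of sections")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(
            f"unknown config sections: {sorted(unknown)}; valid: {sorted(_SECTIONS)}"
        )
    kwargs = {
        name: _build_section(cls, raw.get(name) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    return RunConfig(**kwargs)


def config_to_dict(cfg: RunConfig) -> dict:
    """Plain-dict echo of a config (for metadata sidecars)."""
    return dataclasses.asdict(cfg)
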
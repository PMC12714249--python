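"""Pipeline configuration: one object, one YAML file, every knob.

Defaults reproduce the study settings end to end: 3-cell VRM window, 2.5
degree flatness angle, 25% scene rejection, 10,000-cell / +-0.7 collinearity
screen, 1 m land mask, 70/30 splits x 175 simulations, ntree 215 / mtry 6 /
nodesize 1 / unlimited maxnodes, 0.75/0.50 confidence tiers, 50 m depth
mask. A single global seed funnels every source of randomness.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .rfmc import MCParams, RFParams
from .synthgrid import SynthConfig
from .terrain import TerrainParams

__all__ = ["ThermalConfig", "StackConfig", "MapConfig", "PipelineConfig"]


class ConfigError(ValueError):
    """Invalid configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Invalid or inconsistent data (CLI exit code 1)."""


@dataclass
class ThermalConfig:
    max_cloud: float = 0.25
    min_obs: int = 3


@dataclass
class StackConfig:
    n_cells: int = 10_000
    threshold: float = 0.7
    min_depth: float = 1.0
    priority: list[str] | None = None


@dataclass
class MapConfig:
    high: float = 0.75
    low: float = 0.50
    max_depth: float = 50.0


@dataclass
class PipelineConfig:
    seed: int = 0
    synth: SynthConfig = field(default_factory=SynthConfig)
    terrain: TerrainParams = field(default_factory=TerrainParams)
    thermal: ThermalConfig = field(default_factory=ThermalConfig)
    stack: StackConfig = field(default_factory=StackConfig)
    rf: RFParams = field(default_factory=RFParams)
    mc: MCParams = field(default_factory=MCParams)
    map: MapConfig = field(default_factory=MapConfig)

    def __post_init__(self) -> None:
        # The global seed drives the generator and the Monte-Carlo stream.
        self.synth = dataclasses.replace(self.synth, seed=self.seed)
        self.mc = dataclasses.replace(self.mc, base_seed=self.seed)

    def to_yaml(self, path: str | Path) -> None:
        def clean(obj):
            if dataclasses.is_dataclass(obj):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [clean(v) for v in obj]
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, list):
                return [clean(v) for v in obj]
            return obj

        Path(path).write_text(yaml.safe_dump(clean(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(klass, data):
            if data is None:
                return klass()
            fields = {f.name: f for f in dataclasses.fields(klass)}
            unknown = set(data) - set(fields)
            if unknown:
                raise ConfigError(f"unknown {klass.__name__} keys: {sorted(unknown)}")
            kwargs = {}
            for key, val in data.items():
                if isinstance(val, list) and not isinstance(
                    fields[key].default, list
                ):
                    val = tuple(val)
                if key == "rule_coefficients" and isinstance(val, dict):
                    val = {k: tuple(v) for k, v in val.items()}
                kwargs[key] = val
            try:
                return klass(**kwargs)
            except ValueError as exc:
                raise ConfigError(str(exc)) from exc

        try:
            return cls(
                seed=int(raw.get("seed", 0)),
                synth=build(SynthConfig, raw.get("synth")),
                terrain=build(TerrainParams, raw.get("terrain")),
                thermal=build(ThermalConfig, raw.get("thermal")),
                stack=build(StackConfig, raw.get("stack")),
                rf=build(RFParams, raw.get("rf")),
                mc=build(MCParams, raw.get("mc")),
                map=build(MapConfig, raw.get("map")),
            )
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
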
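"""Single-file pipeline configuration (YAML), shared by all commands."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .raw_io import ExportDialect
from .simulate import SimConfig
from .trial_builder import Geometry

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass
class PipelineConfig:
    """Everything a full pipeline run needs, loadable from one YAML file.

    Defaults reproduce the collector's standard settings: 700 ms
    latency alert, 5000 ms answer limit, 6 practice and 10 experimental
    stimuli, 570 px button separation, 472 px button-to-Next distance.
    """

    dialect: ExportDialect = field(default_factory=ExportDialect)
    geometry: Geometry = field(default_factory=Geometry)
    sim: SimConfig = field(default_factory=SimConfig)
    exclusion_policy: str = "conservative"
    jitter_threshold: float = 0.0
    riemann_method: str = "trapezoid"
    include_nuisance: bool = True
    standardize_outcomes: bool = True
    ambiguous_stimuli: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.exclusion_policy not in ("conservative", "permissive"):
            raise ConfigError(
                f"unknown exclusion policy {self.exclusion_policy!r}")
        if self.riemann_method not in ("trapezoid", "left"):
            raise ConfigError(
                f"unknown Riemann method {self.riemann_method!r}")

    def ambiguity_map(self) -> dict[str, int] | None:
        if self.ambiguous_stimuli:
            amb = set(self.ambiguous_stimuli)
            ids = set(self.sim.stimulus_ids()) | amb
            return {s: int(s in amb) for s in ids}
        return self.sim.ambiguity_map()


_NESTED = {"dialect": ExportDialect, "geometry": Geometry, "sim": SimConfig}


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, list):
        return [_to_plain(v) for v in obj]
    return obj


def dump_config(config: PipelineConfig, path: str | Path) -> None:
    data = _to_plain(asdict(config))
    # the sim block embeds its own geometry; keep the file flat by
    # writing geometry once at top level
    data["sim"].pop("geometry", None)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def _dataclass_from(cls, data: dict):
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name in data:
            v = data[f.name]
            if isinstance(v, list) and f.name in (
                    "zoom_choices", "intertrial_gap_ms"):
                v = tuple(v)
            kwargs[f.name] = v
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    try:
        data = yaml.safe_load(Path(path).read_text()) or {}
    except yaml.YAMLError as e:
        raise ConfigError(f"cannot parse config {path}: {e}") from e
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a mapping")
    kwargs: dict = {}
    geometry = None
    if "geometry" in data:
        geometry = _dataclass_from(Geometry, data.pop("geometry"))
        kwargs["geometry"] = geometry
    if "dialect" in data:
        kwargs["dialect"] = _dataclass_from(ExportDialect, dict(data.pop("dialect")))
    if "sim" in data:
        block = dict(data.pop("sim"))
        if geometry is not None:
            block["geometry"] = geometry
        kwargs["sim"] = _dataclass_from(SimConfig, block)
    elif geometry is not None:
        kwargs["sim"] = SimConfig(geometry=geometry)
    valid = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    kwargs.update(data)
    return PipelineConfig(**kwargs)
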
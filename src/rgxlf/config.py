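"""Structured run configuration with YAML round-trip.

One human-readable file drives the whole pipeline. All defaults equal the
standard protocol values: K=20 background frequencies, event level 0.3,
averaging level 0.1, 90 degree margins, 1028 frames over 720 degrees (CT) or
1024 frames planar, reconstruction grid 512.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, is_dataclass, replace
from pathlib import Path

import yaml

from .exceptions import ConfigurationError
from .phantom import (
    AcquisitionConfig,
    BreathingParams,
    Ellipse,
    PhantomConfig,
    Region,
)

__all__ = ["TraceParams", "GatingParams", "RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class TraceParams:
    K: int = 20
    level: float = 0.3
    margin_degrees: float = 90.0
    heart_band_bpm: tuple[float, float] = (300.0, 700.0)

    def __post_init__(self):
        if self.K < 1:
            raise ConfigurationError("K must be >= 1")
        if not 0 < self.level < 1:
            raise ConfigurationError("event level must lie in (0, 1)")
        if self.margin_degrees < 0:
            raise ConfigurationError("margin must be non-negative")


@dataclass(frozen=True)
class GatingParams:
    select_level: float = 0.3
    avg_level: float = 0.1
    grid_side: int = 512

    def __post_init__(self):
        if not 0 < self.avg_level <= self.select_level < 1:
            raise ConfigurationError("need 0 < avg_level <= select_level < 1")
        if self.grid_side < 16:
            raise ConfigurationError("grid_side too small")


@dataclass(frozen=True)
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    breathing: BreathingParams = field(default_factory=BreathingParams)
    trace: TraceParams = field(default_factory=TraceParams)
    gating: GatingParams = field(default_factory=GatingParams)
    seed: int = 0
    output_dir: str = "rgxlf_out"


def _to_plain(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def _build(cls, data):
    if data is None:
        return cls()
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if f.name in ("body", "cardiac_region", "bone_region"):
            value = Ellipse(**value)
        elif f.name == "lung_regions":
            value = tuple(
                Region(shape=Ellipse(**r["shape"]), attenuation=r["attenuation"])
                for r in value
            )
        elif f.name in ("heart_span_frac", "heart_band_bpm"):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(_to_plain(cfg), sort_keys=False))
    return path


def load_config(path: str | Path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(
        phantom=_build(PhantomConfig, data.get("phantom")),
        acquisition=_build(AcquisitionConfig, data.get("acquisition")),
        breathing=_build(BreathingParams, data.get("breathing")),
        trace=_build(TraceParams, data.get("trace")),
        gating=_build(GatingParams, data.get("gating")),
        seed=int(data.get("seed", 0)),
        output_dir=str(data.get("output_dir", "rgxlf_out")),
    )
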
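"""Run configuration: schema, defaults, YAML loading, validation.

A :class:`RunConfig` drives the whole pipeline (simulate -> sample ->
rasterize -> estimate -> sweep -> evaluate).  Configs are validated before
any stage runs; unknown keys are rejected so typos fail fast.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .estimate import METHODS
from .evaluate import DEFAULT_CELL_SIZES_MM
from .scene import DEFAULT_SCALE

__all__ = ["RunConfig", "LayoutConfig", "SceneConfig", "OutputConfig", "load_config"]


@dataclass
class LayoutConfig:
    plot_side: float = 2.5
    n_per_side: int = 5
    subplot_side: float = 0.5
    crop_side: float = 0.3


@dataclass
class SceneConfig:
    relief_sd: float = 0.005
    ground_correlation_length: float = 0.5
    blades_per_m2: float = 8000.0
    height_cv: float = 0.01
    leaf_width: float = 0.010
    subplot_mean_height_range_mm: tuple[float, float] = (300.0, 500.0)
    stubble_height: float = 0.03
    n_probes: int = 5


@dataclass
class OutputConfig:
    dir: str = "out"
    cloud_format: str = "csv"      # csv | ply | las
    write_clouds: bool = True
    write_dsms: bool = False
    dsm_format: str = "asc"        # asc | tif
    plot: bool = False


@dataclass
class RunConfig:
    """Validated parameters of a full pipeline run."""

    layout: LayoutConfig = field(default_factory=LayoutConfig)
    scene: SceneConfig = field(default_factory=SceneConfig)
    sensors: list[str] = field(default_factory=lambda: ["uav_sfm", "pole_sfm", "lidar"])
    scale: float = DEFAULT_SCALE
    methods: list[str] = field(default_factory=lambda: list(METHODS))
    cell_sizes_mm: list[float] = field(default_factory=lambda: list(DEFAULT_CELL_SIZES_MM))
    seed: int = 0
    alpha: float = 0.01
    output: OutputConfig = field(default_factory=OutputConfig)

    def validate(self) -> "RunConfig":
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        if not self.sensors:
            raise ValueError("at least one sensor is required")
        known_sensors = {"uav_sfm", "pole_sfm", "lidar"}
        unknown = set(self.sensors) - known_sensors
        if unknown:
            raise ValueError(f"unknown sensors {sorted(unknown)}; known: {sorted(known_sensors)}")
        bad = [m for m in self.methods if m not in METHODS]
        if bad:
            raise ValueError(f"unknown methods {bad}; known: {list(METHODS)}")
        if not self.cell_sizes_mm or any(s <= 0 for s in self.cell_sizes_mm):
            raise ValueError("cell_sizes_mm must be a non-empty list of positive sizes")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.output.cloud_format not in ("csv", "ply", "las"):
            raise ValueError(f"unknown cloud format {self.output.cloud_format!r}")
        if self.output.dsm_format not in ("asc", "tif"):
            raise ValueError(f"unknown dsm format {self.output.dsm_format!r}")
        lc = self.layout
        if lc.n_per_side * lc.subplot_side > lc.plot_side + 1e-9:
            raise ValueError("subplot grid does not fit inside the plot")
        if not 0 < lc.crop_side <= lc.subplot_side:
            raise ValueError("crop_side must lie in (0, subplot_side]")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def _build(cls, data: dict, path: str):
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} under {path!r}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        val = data[f.name]
        nested = {"layout": LayoutConfig, "scene": SceneConfig, "output": OutputConfig}
        if f.name in nested and isinstance(val, dict):
            val = _build(nested[f.name], val, f"{path}.{f.name}")
        if f.name == "subplot_mean_height_range_mm":
            val = tuple(val)
        kwargs[f.name] = val
    return cls(**kwargs)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML config (optional) merged with overrides, and validate."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a mapping")
        data.update(loaded)
    for key, val in (overrides or {}).items():
        if val is not None:
            data[key] = val
    cfg = _build(RunConfig, data, "<root>")
    return cfg.validate()
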
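"""End-to-end pipeline: simulate -> sample -> sweep -> evaluate -> artifacts.

Given a validated :class:`~canopyheight.config.RunConfig`, this runs the
measurement sequence (generate the plot, sample every sensor before
harvest, harvest, sample again, evaluate) and writes a deterministic
artifact set: clouds, optional DSMs, truth and estimate tables, sweep
tables, the sensor comparison report, and a run log.  Identical seeds
produce byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import io as chio
from . import scene as sc
from .config import RunConfig
from .evaluate import compare_sensors, plot_mae_curves, sweep
from .raster import make_grid, rasterize_all

logger = logging.getLogger("canopyheight")

__all__ = ["PipelineError", "run_pipeline"]

_SENSOR_FACTORIES = {
    "uav_sfm": sc.uav_sfm_sensor,
    "pole_sfm": sc.pole_sfm_sensor,
    "lidar": sc.lidar_sensor,
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - report the failing stage
                logger.error("stage %s failed: %s", name, exc)
                raise PipelineError(name, str(exc)) from exc
        return wrapper
    return deco


@_stage("simulate")
def _simulate(cfg: RunConfig):
    layout = sc.make_layout(cfg.layout.plot_side, cfg.layout.n_per_side,
                            cfg.layout.subplot_side, cfg.layout.crop_side)
    base = np.random.SeedSequence(int(cfg.seed))
    scene_ss, sensor_ss = base.spawn(2)
    from .evaluate import simulate_plot

    pre, post, truth = simulate_plot(
        scene_ss, layout=layout,
        relief_sd=cfg.scene.relief_sd,
        ground_correlation_length=cfg.scene.ground_correlation_length,
        blades_per_m2=cfg.scene.blades_per_m2,
        height_cv=cfg.scene.height_cv,
        leaf_width=cfg.scene.leaf_width,
        subplot_mean_height_range_mm=cfg.scene.subplot_mean_height_range_mm,
        stubble_height=cfg.scene.stubble_height,
        n_probes=cfg.scene.n_probes,
    )
    seeds = sensor_ss.generate_state(len(cfg.sensors))
    sensors = {
        name: _SENSOR_FACTORIES[name](seed=int(seeds[k]) % (2 ** 31), scale=cfg.scale)
        for k, name in enumerate(cfg.sensors)
    }
    return layout, pre, post, truth, sensors


@_stage("sample")
def _sample(pre, post, sensors):
    return {name: (sc.sample_cloud(pre, s), sc.sample_cloud(post, s))
            for name, s in sensors.items()}


@_stage("sweep")
def _sweep(clouds, layout, truth, cfg: RunConfig):
    return sweep(clouds, layout, truth, methods=cfg.methods,
                 cell_sizes_mm=cfg.cell_sizes_mm)


@_stage("evaluate")
def _evaluate(table, cfg: RunConfig):
    if len(cfg.sensors) < 2:
        logger.info("single sensor configured; skipping cross-sensor comparison")
        return None
    return compare_sensors(table, alpha=cfg.alpha)


@_stage("write")
def _write(out: Path, cfg: RunConfig, truth, clouds, table, report, layout):
    out.mkdir(parents=True, exist_ok=True)
    truth.to_frame().to_csv(out / "truth.csv", index=False)
    if cfg.output.write_clouds:
        cloud_dir = out / "clouds"
        cloud_dir.mkdir(exist_ok=True)
        for name, (pre_cloud, post_cloud) in clouds.items():
            ext = cfg.output.cloud_format
            chio.write_point_cloud(pre_cloud, cloud_dir / f"{name}_pre_harvest.{ext}")
            chio.write_point_cloud(post_cloud, cloud_dir / f"{name}_post_harvest.{ext}")
    if cfg.output.write_dsms:
        dsm_dir = out / "dsms"
        dsm_dir.mkdir(exist_ok=True)
        writer = chio.write_asc if cfg.output.dsm_format == "asc" else chio.write_geotiff
        for name, (pre_cloud, post_cloud) in clouds.items():
            for cell_mm in cfg.cell_sizes_mm:
                grid = make_grid(layout.extent, cell_mm / 1000.0)
                for epoch, cloud in (("pre", pre_cloud), ("post", post_cloud)):
                    for agg, dsm in rasterize_all(cloud, grid).items():
                        writer(dsm, dsm_dir / f"{name}_{epoch}_{cell_mm:g}mm_{agg}.{cfg.output.dsm_format}")
    table.detail.to_csv(out / "sweep_detail.csv", index=False)
    table.summary.to_csv(out / "sweep_summary.csv", index=False)
    if report is not None:
        report.best.to_csv(out / "comparison_best.csv", index=False)
        report.to_json(out / "comparison.json")
    if cfg.output.plot:
        plot_mae_curves(table.summary, out / "mae_vs_cellsize.png")


def run_pipeline(cfg: RunConfig, out_dir=None):
    """Run the full pipeline; returns (SweepTable, ComparisonReport).

    Artifacts land under ``out_dir`` (default: ``cfg.output.dir``).  Any
    stage failure raises :class:`PipelineError` naming the stage.
    """
    cfg.validate()
    out = Path(out_dir if out_dir is not None else cfg.output.dir)
    handler = logging.FileHandler(out / "run.log", mode="w") if _ensure_dir(out) else None
    if handler is not None:
        handler.setLevel(logging.INFO)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
        prev_level = logger.level
        logger.setLevel(logging.INFO)
    try:
        layout, pre, post, truth, sensors = _simulate(cfg)
        clouds = _sample(pre, post, sensors)
        table = _sweep(clouds, layout, truth, cfg)
        report = _evaluate(table, cfg)
        _write(out, cfg, truth, clouds, table, report, layout)
    finally:
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()
            logger.setLevel(prev_level)
    return table, report


def _ensure_dir(out: Path) -> bool:
    out.mkdir(parents=True, exist_ok=True)
    return True
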
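"""Accuracy evaluation: method x resolution x sensor sweeps and statistics.

For every combination of sensor model, selection method, and DSM cell size,
the sweep rasterizes the paired before/after clouds, differences the DSMs,
summarises estimates per subplot, and scores them against ruler truth as
per-subplot absolute errors.  Summaries report MAE +/- SD, where SD is the
sample standard deviation of the per-subplot absolute errors.

Statistical comparisons between sensors follow the study protocol: one-way
ANOVA on the per-subplot absolute errors at each sensor's best settings,
followed by Tukey's HSD multiple-comparison test (alpha = 0.01), plus the
Pearson correlation of estimated versus measured heights.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import scene as sc
from .estimate import METHODS, estimate_height, subplot_summary
from .raster import PointCloud, make_grid, rasterize_all
from .scene import CanopyScene, SensorModel, SubplotLayout, TruthTable

logger = logging.getLogger("canopyheight")

#: the seven DSM resolutions of the study, mm
DEFAULT_CELL_SIZES_MM = (5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 100.0)

__all__ = [
    "DEFAULT_CELL_SIZES_MM",
    "ErrorStats",
    "SweepTable",
    "AnovaTukeyResult",
    "ComparisonReport",
    "absolute_error_stats",
    "sweep",
    "anova_tukey",
    "correlation",
    "compare_sensors",
    "replicate_experiment",
    "plot_mae_curves",
]


# ---------------------------------------------------------------------------
# error statistics
# ---------------------------------------------------------------------------

@dataclass
class ErrorStats:
    """MAE and SD (mm) of per-subplot absolute errors, plus the errors."""

    mae_mm: float
    sd_mm: float
    errors: pd.DataFrame  # subplot_id, estimate_mm, truth_mm, abs_error_mm


def absolute_error_stats(estimates, truth: TruthTable) -> ErrorStats:
    """Per-subplot |estimate - truth| with their mean (MAE) and sample SD.

    ``estimates`` is a :class:`~canopyheight.estimate.SubplotEstimates` (only
    subplots with valid cells are scored) or any frame with columns
    subplot_id / estimate_mm.
    """
    frame = estimates.valid() if hasattr(estimates, "valid") else pd.DataFrame(estimates)
    truth_frame = truth.to_frame()
    merged = frame.merge(truth_frame, on="subplot_id", how="left", validate="1:1")
    if merged["truth_mm"].isna().any():
        raise ValueError("estimate subplot ids not present in the truth table")
    merged = merged.copy()
    merged["abs_error_mm"] = (merged["estimate_mm"] - merged["truth_mm"]).abs()
    errs = merged["abs_error_mm"].to_numpy()
    if errs.size == 0:
        raise ValueError("no valid subplot estimates to score")
    sd = float(np.std(errs, ddof=1)) if errs.size > 1 else 0.0
    cols = ["subplot_id", "estimate_mm", "truth_mm", "abs_error_mm"]
    return ErrorStats(mae_mm=float(errs.mean()), sd_mm=sd, errors=merged[cols])


# ---------------------------------------------------------------------------
# the factorial sweep
# ---------------------------------------------------------------------------

@dataclass
class SweepTable:
    """Full factorial error table over (sensor, method, cell size).

    ``detail`` holds one row per (sensor, method, cell_size, subplot) with
    estimate, truth, and absolute error; ``summary`` one row per combination
    with MAE +/- SD and the error range across subplots.
    """

    detail: pd.DataFrame
    summary: pd.DataFrame


def sweep(clouds: dict[str, tuple[PointCloud, PointCloud]], layout: SubplotLayout,
          truth: TruthTable, methods=None, cell_sizes_mm=DEFAULT_CELL_SIZES_MM) -> SweepTable:
    """Score every (sensor, method, cell size) combination.

    ``clouds`` maps sensor name to its (pre-harvest, post-harvest) pair.
    Before- and after-harvest DSMs are built on the identical grid so the
    difference is cellwise.  With the four methods and seven study cell
    sizes this yields 28 summary rows per sensor.
    """
    if methods is None:
        methods = list(METHODS)
    method_tags = [METHODS[m] if isinstance(m, str) else m for m in methods]
    if any(s <= 0 for s in cell_sizes_mm):
        raise ValueError("cell sizes must be positive")

    detail_rows = []
    for sensor_name, pair in clouds.items():
        if len(pair) != 2 or pair[0] is None or pair[1] is None:
            raise ValueError(f"sensor {sensor_name!r} is missing an epoch")
        before, after = pair
        for cell_mm in cell_sizes_mm:
            grid = make_grid(layout.extent, cell_mm / 1000.0)
            dsm_before = rasterize_all(before, grid)
            dsm_after = rasterize_all(after, grid)
            for tag in method_tags:
                hr = estimate_height(dsm_before[tag.aggregator_before],
                                     dsm_after[tag.aggregator_after], tag)
                est = subplot_summary(hr, layout)
                st = absolute_error_stats(est, truth)
                df = st.errors.copy()
                df.insert(0, "sensor", sensor_name)
                df.insert(1, "method", tag.name)
                df.insert(2, "cell_size_mm", cell_mm)
                df["n_valid_cells"] = est.valid()["n_valid_cells"].to_numpy()
                detail_rows.append(df)
    detail = pd.concat(detail_rows, ignore_index=True)
    summary = summarize_detail(detail)
    return SweepTable(detail=detail, summary=summary)


def summarize_detail(detail: pd.DataFrame) -> pd.DataFrame:
    """Collapse a detail table to MAE/SD/range per (sensor, method, cell size)."""
    g = detail.groupby(["sensor", "method", "cell_size_mm"], sort=True)["abs_error_mm"]
    summary = g.agg(
        mae_mm="mean",
        sd_mm=lambda e: float(np.std(e, ddof=1)) if len(e) > 1 else 0.0,
        min_abs_error_mm="min",
        max_abs_error_mm="max",
        n_subplots="size",
    ).reset_index()
    return summary


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass
class AnovaTukeyResult:
    """One-way ANOVA F/p plus Tukey-HSD adjusted pairwise comparisons."""

    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_a, group_b, mean_diff, p_adj, significant
    alpha: float


def anova_tukey(error_groups: dict[str, np.ndarray], alpha: float = 0.01) -> AnovaTukeyResult:
    """One-way ANOVA followed by Tukey's multiple comparison test.

    ``error_groups`` maps a label to its per-subplot absolute errors.  If
    every group has zero variance (degenerate input) the convention p = 1 is
    reported with a warning and no pair is flagged significant.
    """
    names = list(error_groups)
    groups = [np.asarray(error_groups[k], dtype=float) for k in names]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("each group needs at least two observations")

    pooled = np.concatenate(groups)
    degenerate = all(np.ptp(g) == 0 for g in groups)
    if degenerate:
        warnings.warn("all groups have zero variance; reporting p = 1", stacklevel=2)
        f_stat, p_val = float("nan"), 1.0
        pairs = [(a, b, float(np.mean(error_groups[b]) - np.mean(error_groups[a])), 1.0, False)
                 for i, a in enumerate(names) for b in names[i + 1:]]
        pairwise = pd.DataFrame(pairs, columns=["group_a", "group_b", "mean_diff",
                                                "p_adj", "significant"])
        return AnovaTukeyResult(f_stat, p_val, pairwise, alpha)

    f_stat, p_val = sps.f_oneway(*groups)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    labels = np.concatenate([np.full(g.size, name, dtype=object)
                             for name, g in zip(names, groups)])
    res = pairwise_tukeyhsd(pooled, labels, alpha=alpha)
    pairwise = pd.DataFrame({
        "group_a": res.groupsunique[np.asarray(res._multicomp.pairindices[0])],
        "group_b": res.groupsunique[np.asarray(res._multicomp.pairindices[1])],
        "mean_diff": res.meandiffs,
        "p_adj": np.clip(res.pvalues, 0.0, 1.0),
        "significant": res.reject,
    })
    return AnovaTukeyResult(float(f_stat), float(p_val), pairwise, alpha)


def correlation(estimates_mm, truth_mm) -> float:
    """Pearson product-moment correlation of estimates against truth.

    Returns NaN (with a warning) when either input has zero variance.
    """
    a = np.asarray(estimates_mm, dtype=float)
    b = np.asarray(truth_mm, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length vectors of at least 3 values")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("zero variance input; correlation undefined", stacklevel=2)
        return float("nan")
    return float(sps.pearsonr(a, b).statistic)


# ---------------------------------------------------------------------------
# sensor comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonReport:
    """Best settings and cross-sensor significance at those settings."""

    best: pd.DataFrame  # sensor, method, cell_size_mm, mae_mm, sd_mm, pearson_r
    anova: AnovaTukeyResult
    alpha: float = 0.01

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "best": self.best.to_dict(orient="records"),
            "anova": {
                "f_statistic": self.anova.f_statistic,
                "p_value": self.anova.p_value,
                "pairwise": self.anova.pairwise.to_dict(orient="records"),
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def compare_sensors(table: SweepTable, alpha: float = 0.01) -> ComparisonReport:
    """Select each sensor's error-minimising settings and compare sensors.

    Per sensor, the (method, cell size) minimising MAE is selected (exact
    ties resolved toward the larger cell size, which leaves fewer empty
    cells, and logged); the per-subplot absolute errors at those settings
    feed one-way ANOVA + Tukey HSD across sensors, and the Pearson r of
    estimates versus truth is reported per sensor.
    """
    sensors = table.summary["sensor"].unique()
    if len(sensors) < 2:
        raise ValueError("need sweeps for at least two sensors")
    best_rows = []
    groups: dict[str, np.ndarray] = {}
    for sensor in sensors:
        sub = table.summary[table.summary["sensor"] == sensor]
        if sub.empty:
            raise ValueError(f"incomplete sweep for sensor {sensor!r}")
        min_mae = sub["mae_mm"].min()
        ties = sub[sub["mae_mm"] == min_mae]
        if len(ties) > 1:
            logger.info("compare_sensors[%s]: %d-way MAE tie; choosing largest cell size",
                        sensor, len(ties))
        row = ties.sort_values("cell_size_mm", ascending=False).iloc[0]
        sel = table.detail[
            (table.detail["sensor"] == sensor)
            & (table.detail["method"] == row["method"])
            & (table.detail["cell_size_mm"] == row["cell_size_mm"])
        ]
        groups[sensor] = sel["abs_error_mm"].to_numpy()
        r = correlation(sel["estimate_mm"].to_numpy(), sel["truth_mm"].to_numpy())
        best_rows.append({
            "sensor": sensor,
            "method": row["method"],
            "cell_size_mm": float(row["cell_size_mm"]),
            "mae_mm": float(row["mae_mm"]),
            "sd_mm": float(row["sd_mm"]),
            "pearson_r": r,
        })
    best = pd.DataFrame(best_rows).sort_values("mae_mm").reset_index(drop=True)
    return ComparisonReport(best=best, anova=anova_tukey(groups, alpha=alpha), alpha=alpha)


# ---------------------------------------------------------------------------
# the replicate experiment (study conditions end-to-end)
# ---------------------------------------------------------------------------

@dataclass
class ReplicateResult:
    """Pooled outputs of an n-replicate synthetic study run.

    ``summary`` averages each combination's per-replicate MAE over
    replicates (column replicate_mean_mae_mm); ``detail`` pools per-subplot
    rows with a replicate column; ``report`` compares sensors on the pooled
    errors at the settings minimising the replicate-mean MAE.
    """

    detail: pd.DataFrame
    per_replicate: pd.DataFrame
    summary: pd.DataFrame
    report: ComparisonReport
    truth_range_mm: tuple[float, float] = field(default=(0.0, 0.0))


def simulate_plot(seed, layout: SubplotLayout | None = None, *,
                  relief_sd: float = 0.005, ground_correlation_length: float = 0.5,
                  blades_per_m2: float = 8000.0, height_cv: float = 0.01,
                  leaf_width: float = 0.010,
                  subplot_mean_height_range_mm: tuple[float, float] = (300.0, 500.0),
                  stubble_height: float = 0.03, n_probes: int = 5,
                  ) -> tuple[CanopyScene, CanopyScene, TruthTable]:
    """Generate one study plot: pre-harvest scene, post-harvest scene, truth.

    Subplot mean heights are drawn uniformly from
    ``subplot_mean_height_range_mm`` so the estimate-truth correlation has
    spread to work with, as in a real sward with patchy growth.
    """
    if layout is None:
        layout = sc.make_layout(2.5, 5, 0.5, 0.3)
    parent = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss = parent.spawn(4)
    ground = sc.generate_ground(layout, relief_sd, ground_correlation_length, ss[0])
    lo, hi = subplot_mean_height_range_mm
    means = np.random.default_rng(ss[1]).uniform(lo, hi, size=layout.n_subplots)
    pre = sc.generate_canopy(ground, layout, means, height_cv, blades_per_m2,
                             leaf_width, seed=ss[2])
    truth = sc.ruler_truth(pre, n_probes=n_probes, seed=ss[3])
    post = sc.harvest(pre, stubble_height)
    return pre, post, truth


def replicate_experiment(n_replicates: int = 5, seed: int = 0,
                         scale: float = sc.DEFAULT_SCALE,
                         sensors: dict[str, SensorModel] | None = None,
                         cell_sizes_mm=DEFAULT_CELL_SIZES_MM, methods=None,
                         alpha: float = 0.01, **scene_kwargs) -> ReplicateResult:
    """Run the full study on ``n_replicates`` independent synthetic plots.

    Each replicate generates a fresh plot and truth, samples every sensor
    before and after harvest, and sweeps methods x cell sizes.  Combinations
    are compared on the *replicate-mean* MAE (single-replicate reversals are
    expected and tolerated); the sensor comparison report pools per-subplot
    errors across replicates at each sensor's best settings.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    base = np.random.SeedSequence(int(seed))
    rep_seeds = base.spawn(n_replicates)
    details = []
    truth_lo, truth_hi = np.inf, -np.inf
    for r, rseed in enumerate(rep_seeds):
        scene_ss, sensor_ss = rseed.spawn(2)
        pre, post, truth = simulate_plot(scene_ss, **scene_kwargs)
        truth_lo = min(truth_lo, truth.heights_mm.min())
        truth_hi = max(truth_hi, truth.heights_mm.max())
        if sensors is None:
            rep_sensors = sc.default_sensors(seed=int(sensor_ss.generate_state(1)[0]) % (2 ** 31),
                                             scale=scale)
        else:
            rep_sensors = sensors
        clouds = {name: (sc.sample_cloud(pre, s), sc.sample_cloud(post, s))
                  for name, s in rep_sensors.items()}
        tab = sweep(clouds, pre.layout, truth, methods=methods,
                    cell_sizes_mm=cell_sizes_mm)
        d = tab.detail.copy()
        d.insert(0, "replicate", r)
        details.append(d)
        logger.info("replicate %d/%d complete", r + 1, n_replicates)
    detail = pd.concat(details, ignore_index=True)

    per_rep = (
        detail.groupby(["sensor", "method", "cell_size_mm", "replicate"], sort=True)
        ["abs_error_mm"].mean().rename("mae_mm").reset_index()
    )
    summary = (
        per_rep.groupby(["sensor", "method", "cell_size_mm"], sort=True)["mae_mm"]
        .agg(replicate_mean_mae_mm="mean", replicate_sd_mae_mm=lambda e: float(np.std(e, ddof=1)) if len(e) > 1 else 0.0)
        .reset_index()
    )

    pooled = SweepTable(
        detail=detail,
        summary=summarize_detail(detail).merge(
            summary, on=["sensor", "method", "cell_size_mm"]
        ).assign(mae_mm=lambda df: df["replicate_mean_mae_mm"]),
    )
    report = compare_sensors(pooled, alpha=alpha)
    return ReplicateResult(detail=detail, per_replicate=per_rep, summary=summary,
                           report=report, truth_range_mm=(float(truth_lo), float(truth_hi)))


def plot_mae_curves(summary: pd.DataFrame, path, value_col: str | None = None) -> None:
    """Plot MAE versus DSM cell size, one panel per sensor, one line per method."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if value_col is None:
        value_col = "replicate_mean_mae_mm" if "replicate_mean_mae_mm" in summary else "mae_mm"
    sensors = summary["sensor"].unique()
    fig, axes = plt.subplots(1, len(sensors), figsize=(4.2 * len(sensors), 3.6),
                             sharey=True, squeeze=False)
    for ax, sensor in zip(axes[0], sensors):
        sub = summary[summary["sensor"] == sensor]
        for method, grp in sub.groupby("method"):
            grp = grp.sort_values("cell_size_mm")
            ax.plot(grp["cell_size_mm"], grp[value_col], marker="o", label=method)
        ax.set_title(sensor)
        ax.set_xlabel("DSM cell size (mm)")
        ax.set_xscale("log")
    axes[0][0].set_ylabel("MAE (mm)")
    axes[0][-1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
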
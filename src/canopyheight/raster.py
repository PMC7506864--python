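"""Point-cloud rasterization to digital surface models (DSMs).

A DSM is a regular grid in which each cell stores one representative height
selected from the points whose (x, y) coordinates fall inside the cell.
Three per-cell selection rules are supported — maximum, mean, and minimum —
which are the building blocks of the four canopy-height estimation methods
(see :mod:`canopyheight.estimate`).

Conventions
-----------
* Cells are half-open intervals: cell (row i, col j) spans
  ``[x0 + j*c, x0 + (j+1)*c) x [y0 + i*c, y0 + (i+1)*c)``, with the origin at
  the grid's minimum corner, x increasing with columns and y with rows.
  A point exactly on a shared edge belongs to the cell on the +x/+y side.
* Cells containing no points are masked nodata and never interpolated.
* Heights are metres throughout; unit conversion happens only at reporting
  boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("canopyheight")

AGGREGATORS = ("max", "mean", "min")

__all__ = [
    "AGGREGATORS",
    "PointCloud",
    "GridSpec",
    "DSM",
    "make_grid",
    "rasterize",
    "rasterize_all",
    "point_density",
]


@dataclass
class PointCloud:
    """N x (x, y, z) coordinates in metres, with provenance tags.

    Parameters
    ----------
    xyz : (N, 3) float array
        Point coordinates in metres.  Must be finite.
    sensor_tag : str
        Free-form sensor identifier (e.g. ``"uav_sfm"``).
    epoch : str
        ``"pre_harvest"`` or ``"post_harvest"`` (empty when unknown).
    """

    xyz: np.ndarray
    sensor_tag: str = ""
    epoch: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        if self.xyz.size == 0:
            self.xyz = self.xyz.reshape(0, 3)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError(f"xyz must be an (N, 3) array, got {self.xyz.shape}")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("point cloud contains non-finite coordinates")

    def __len__(self) -> int:
        return self.xyz.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster grid (row-major from the min corner)."""

    origin_xy: tuple[float, float]
    cell_size: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) rectangle covered by the grid."""
        x0, y0 = self.origin_xy
        return (x0, y0, x0 + self.n_cols * self.cell_size, y0 + self.n_rows * self.cell_size)

    @property
    def x_centers(self) -> np.ndarray:
        return self.origin_xy[0] + (np.arange(self.n_cols) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.origin_xy[1] + (np.arange(self.n_rows) + 0.5) * self.cell_size

    def same_geometry(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            self.n_cols == other.n_cols
            and self.n_rows == other.n_rows
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin_xy[0] - other.origin_xy[0]) <= tol
            and abs(self.origin_xy[1] - other.origin_xy[1]) <= tol
        )


@dataclass
class DSM:
    """Gridded surface heights with a nodata mask.

    ``values`` holds heights in metres; entries where ``mask`` is True carry
    no data (the stored number there is undefined).  ``aggregator`` records
    which per-cell selection rule produced the surface.
    """

    values: np.ndarray
    mask: np.ndarray
    grid: GridSpec
    aggregator: str
    n_dropped_points: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        expected = (self.grid.n_rows, self.grid.n_cols)
        if self.values.shape != expected or self.mask.shape != expected:
            raise ValueError(
                f"values/mask shape {self.values.shape} does not match grid {expected}"
            )
        if self.aggregator not in AGGREGATORS:
            raise ValueError(f"aggregator must be one of {AGGREGATORS}")

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.MaskedArray(self.values, mask=self.mask)


def make_grid(extent: tuple[float, float, float, float], cell_size: float) -> GridSpec:
    """Build a grid of square cells tiling ``extent`` = (x0, y0, x1, y1).

    If a side is not an integer multiple of ``cell_size`` the grid is expanded
    to the next multiple (the origin is kept fixed) and the expansion logged.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    x0, y0, x1, y1 = extent
    if x1 <= x0 or y1 <= y0:
        raise ValueError("extent must have positive width and height")
    n_cols = _n_cells(x1 - x0, cell_size, "x")
    n_rows = _n_cells(y1 - y0, cell_size, "y")
    return GridSpec(origin_xy=(x0, y0), cell_size=cell_size, n_cols=n_cols, n_rows=n_rows)


def _n_cells(side: float, cell: float, axis: str) -> int:
    ratio = side / cell
    n = int(round(ratio))
    if abs(ratio - n) > 1e-9:
        n = int(np.ceil(ratio - 1e-9))
        logger.info(
            "extent side %.6g m is not a multiple of cell %.6g m along %s; "
            "expanded to %d cells (%.6g m)",
            side, cell, axis, n, n * cell,
        )
    return max(n, 1)


def _cell_index(cloud: PointCloud, grid: GridSpec) -> tuple[np.ndarray, np.ndarray, int]:
    """Flat cell index per in-extent point; also the kept-point selector."""
    x0, y0 = grid.origin_xy
    c = grid.cell_size
    col = np.floor((cloud.x - x0) / c).astype(np.int64)
    row = np.floor((cloud.y - y0) / c).astype(np.int64)
    inside = (col >= 0) & (col < grid.n_cols) & (row >= 0) & (row < grid.n_rows)
    n_dropped = int(len(cloud) - inside.sum())
    if n_dropped:
        logger.info("rasterize: dropped %d points outside the grid extent", n_dropped)
    flat = row[inside] * grid.n_cols + col[inside]
    return flat, inside, n_dropped


def _grouped_stats(flat: np.ndarray, z: np.ndarray, n_cells: int) -> dict[str, np.ndarray]:
    """Per-cell min/mean/max of z grouped by flat cell index (one sort)."""
    out = {}
    if flat.size == 0:
        nan = np.full(n_cells, np.nan)
        return {"min": nan.copy(), "mean": nan.copy(), "max": nan.copy(), "count": np.zeros(n_cells, dtype=np.int64)}
    order = np.argsort(flat, kind="stable")
    fs = flat[order]
    zs = z[order]
    starts = np.flatnonzero(np.diff(fs)) + 1
    starts = np.concatenate(([0], starts))
    cells = fs[starts]
    counts = np.diff(np.concatenate((starts, [fs.size])))
    mins = np.minimum.reduceat(zs, starts)
    maxs = np.maximum.reduceat(zs, starts)
    sums = np.add.reduceat(zs, starts)
    for name, vals in (("min", mins), ("max", maxs), ("mean", sums / counts)):
        full = np.full(n_cells, np.nan)
        full[cells] = vals
        out[name] = full
    count_full = np.zeros(n_cells, dtype=np.int64)
    count_full[cells] = counts
    out["count"] = count_full
    return out


def rasterize_all(cloud: PointCloud, grid: GridSpec) -> dict[str, DSM]:
    """Rasterize once and return all three aggregations (shared binning).

    More efficient than three :func:`rasterize` calls when a sweep needs the
    maximum, mean, and minimum surfaces of the same cloud on the same grid.
    """
    flat, inside, n_dropped = _cell_index(cloud, grid)
    z = cloud.z[inside]
    n_cells = grid.n_rows * grid.n_cols
    stats = _grouped_stats(flat, z, n_cells)
    shape = (grid.n_rows, grid.n_cols)
    mask = (stats["count"] == 0).reshape(shape)
    n_empty = int(mask.sum())
    if n_empty:
        logger.info("rasterize: %d of %d cells are empty (nodata)", n_empty, n_cells)
    out = {}
    for agg in AGGREGATORS:
        values = stats[agg].reshape(shape).copy()
        values[mask] = np.nan
        out[agg] = DSM(values=values, mask=mask.copy(), grid=grid,
                       aggregator=agg, n_dropped_points=n_dropped)
    return out


def rasterize(cloud: PointCloud, grid: GridSpec, aggregator: str) -> DSM:
    """Convert a point cloud to a DSM with one per-cell selection rule.

    Each unmasked cell holds ``aggregator`` (max | mean | min) applied to the
    z of all points whose (x, y) fall in the cell under the half-open rule;
    empty cells are masked nodata.  Points outside the grid are dropped and
    counted in a log record.  An empty cloud yields a fully masked DSM.
    """
    if aggregator not in AGGREGATORS:
        raise ValueError(f"aggregator must be one of {AGGREGATORS}, got {aggregator!r}")
    return rasterize_all(cloud, grid)[aggregator]


def point_density(cloud: PointCloud, area_cm2: float) -> float:
    """Points per cm^2 over a reference area given in cm^2."""
    if area_cm2 <= 0:
        raise ValueError("area must be positive")
    return len(cloud) / area_cm2
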
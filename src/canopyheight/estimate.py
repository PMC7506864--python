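"""Canopy height estimation by DSM differencing.

Grass height is estimated cellwise as (pre-harvest DSM) - (post-harvest
DSM).  Four selection methods are defined by which per-cell aggregation
rule builds each epoch's DSM:

==================  ===============  ==============
method              before harvest   after harvest
==================  ===============  ==============
maximum             max              max
average             mean             mean
minimum             min              min
maximum_minimum     max              min
==================  ===============  ==============

The maximum-minimum method differences the canopy-top surface against the
lowest post-harvest returns (ideally the ground reached between stubble
leaves), so it approximates true leaf-tip-to-ground height; the others carry
biases from stubble, canopy interior returns, or reconstruction noise.

Estimates are reported in mm.  The residual stubble height is *not* added
back: the raw DSM difference is compared against ruler height, and the bias
this induces is left visible in the evaluation reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import DSM, GridSpec
from .scene import SubplotLayout

logger = logging.getLogger("canopyheight")

__all__ = [
    "MethodTag",
    "METHODS",
    "HeightRaster",
    "SubplotEstimates",
    "estimate_height",
    "subplot_summary",
]


@dataclass(frozen=True)
class MethodTag:
    """One of the four legal (before, after) aggregator combinations."""

    name: str
    aggregator_before: str
    aggregator_after: str


METHODS: dict[str, MethodTag] = {
    "maximum": MethodTag("maximum", "max", "max"),
    "average": MethodTag("average", "mean", "mean"),
    "minimum": MethodTag("minimum", "min", "min"),
    "maximum_minimum": MethodTag("maximum_minimum", "max", "min"),
}


@dataclass
class HeightRaster:
    """Per-cell estimated grass height in mm, masked where either DSM was."""

    values_mm: np.ndarray
    mask: np.ndarray
    grid: GridSpec
    method: MethodTag


@dataclass
class SubplotEstimates:
    """Per-subplot estimated heights over the centered crop windows.

    ``frame`` columns: subplot_id, estimate_mm, n_valid_cells.  Subplots with
    zero valid cells keep their row with NaN estimate and are flagged in the
    log; consumers should filter on ``n_valid_cells >= 1``.
    """

    frame: pd.DataFrame
    method: MethodTag
    cell_size_mm: float

    def valid(self) -> pd.DataFrame:
        return self.frame[self.frame["n_valid_cells"] >= 1]

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out.insert(1, "method", self.method.name)
        out.insert(2, "cell_size_mm", self.cell_size_mm)
        return out


def estimate_height(dsm_before: DSM, dsm_after: DSM, method: MethodTag) -> HeightRaster:
    """Cellwise (before - after) in mm under one selection method.

    Both DSMs must share the same grid geometry and carry the aggregators the
    method prescribes.  Cells masked in either epoch are masked in the
    result.  Negative differences are retained (clipping would bias the
    methods differently) and counted in a log record.
    """
    if not dsm_before.grid.same_geometry(dsm_after.grid):
        raise ValueError("before/after DSMs are on different grids")
    if dsm_before.aggregator != method.aggregator_before:
        raise ValueError(
            f"method {method.name!r} needs a {method.aggregator_before!r} DSM before "
            f"harvest, got {dsm_before.aggregator!r}"
        )
    if dsm_after.aggregator != method.aggregator_after:
        raise ValueError(
            f"method {method.name!r} needs a {method.aggregator_after!r} DSM after "
            f"harvest, got {dsm_after.aggregator!r}"
        )
    mask = dsm_before.mask | dsm_after.mask
    values = np.where(mask, np.nan, (dsm_before.values - dsm_after.values) * 1000.0)
    n_negative = int(np.sum(values[~mask] < 0)) if (~mask).any() else 0
    if n_negative:
        logger.info("estimate_height[%s]: %d unmasked cells have negative estimates",
                    method.name, n_negative)
    return HeightRaster(values_mm=values, mask=mask, grid=dsm_before.grid, method=method)


def subplot_summary(raster: HeightRaster, layout: SubplotLayout) -> SubplotEstimates:
    """Average cell estimates over each subplot's centered crop window.

    A cell belongs to a crop window when its *center* falls inside the
    window (half-open on the +x/+y edges).  The subplot value is the
    arithmetic mean of unmasked member cells; subplots with no valid cell
    are flagged and carry NaN.
    """
    grid = raster.grid
    gx0, gy0, gx1, gy1 = grid.extent
    lx0, ly0, lx1, ly1 = layout.extent
    if lx0 < gx0 - 1e-9 or ly0 < gy0 - 1e-9 or lx1 > gx1 + 1e-9 or ly1 > gy1 + 1e-9:
        raise ValueError("layout extent is not covered by the raster grid")
    xc = grid.x_centers
    yc = grid.y_centers
    rows = []
    for idx in range(layout.n_subplots):
        cx0, cy0, cx1, cy1 = layout.crop_window(idx)
        in_x = (xc >= cx0) & (xc < cx1)
        in_y = (yc >= cy0) & (yc < cy1)
        block = raster.values_mm[np.ix_(in_y, in_x)]
        bmask = raster.mask[np.ix_(in_y, in_x)]
        n_valid = int((~bmask).sum())
        if n_valid == 0:
            logger.warning("subplot %d: no valid cells in crop window; excluded", idx)
            est = np.nan
        else:
            est = float(block[~bmask].mean())
        rows.append((idx, est, n_valid))
    frame = pd.DataFrame(rows, columns=["subplot_id", "estimate_mm", "n_valid_cells"])
    return SubplotEstimates(frame=frame, method=raster.method,
                            cell_size_mm=grid.cell_size * 1000.0)
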
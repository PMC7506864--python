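"""Synthetic grass-canopy scenes and sensor sampling models.

This module generates plot-scale grass scenes with known per-subplot height
truth and samples them with models of three measurement systems — UAV-borne
structure-from-motion (SfM), pole-camera SfM, and a hand-held scanning
LiDAR — so the full estimation pipeline can be exercised and validated
without field data.

The simulated world is a 2.5 m x 2.5 m, almost flat plot subdivided into a
5 x 5 grid of ~50 cm subplots.  Grass is represented as vertical leaf-blade
elements (~10 mm wide) whose tip heights above local ground follow a
lognormal distribution per subplot.  Harvest truncates every blade to a
fixed stubble height (3 cm by default).  Ruler truth is the mean tip height
of a few probed blades per subplot, mimicking manual measurement.

Sensor models
-------------
Both samplers draw uniformly distributed (x, y) measurement locations at a
configured areal density and decide per point whether the return comes from
the canopy surface or the ground:

* SfM reconstructs a smooth canopy *surface* that sits at or below the true
  upper envelope (the max blade-tip surface within a small smoothing
  radius).  Because photogrammetry cannot triangulate individual swaying
  leaf tips, the reconstructed surface dips below the envelope by a
  spatially correlated, non-negative depth field that touches zero only in
  patches; a coarse DSM cell usually contains such a patch (its max
  recovers the envelope) while a fine cell does not (the tip height is
  underestimated).  The ground is visible only with a small probability (it
  is occluded by the sward, especially by post-harvest stubble).  On top of
  this, all SfM points carry a correlated vertical error field (wind/motion
  artefacts at decimetre scale) plus a small independent per-point term.
* LiDAR beams hit a leaf with probability equal to the local canopy cover
  inside the beam footprint and otherwise pass between the leaves to the
  ground.  Leaf returns are averaged over several revisits of the same spot
  (the scanner measures each location many times), which both smooths the
  surface and shrinks the vertical noise.  The narrow beam penetrates deeper
  into the canopy-surface height distribution than the SfM envelope, so its
  leaf-return depth scale is larger.

Every generator and sampler is deterministic for a fixed seed; random
streams are split per subsystem so changing one does not perturb another.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .raster import PointCloud

logger = logging.getLogger("canopyheight")

PRE_HARVEST = "pre_harvest"
POST_HARVEST = "post_harvest"

#: smoothing radius (m) defining the canopy upper envelope
ENVELOPE_RADIUS = 0.025
#: ground elevations are clipped to +/- this multiple of relief_sd ("almost flat")
GROUND_CLIP_SD = 4.0

__all__ = [
    "SubplotLayout",
    "GroundModel",
    "LeafBlade",
    "CanopyScene",
    "SensorModel",
    "TruthTable",
    "make_layout",
    "generate_ground",
    "generate_canopy",
    "harvest",
    "ruler_truth",
    "sample_sfm",
    "sample_lidar",
    "sample_cloud",
    "uav_sfm_sensor",
    "pole_sfm_sensor",
    "lidar_sensor",
    "default_sensors",
]


# ---------------------------------------------------------------------------
# plot layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubplotLayout:
    """Square plot subdivided into a row-major grid of square subplots.

    Subplot (row i, col j) has flat id ``i * n_per_side + j`` and occupies
    ``[x0 + j*s, x0 + (j+1)*s) x [y0 + i*s, y0 + (i+1)*s)`` where ``s`` is
    ``subplot_side``.  Each subplot carries a centered square comparison
    window of side ``crop_side`` used when summarising estimates, to avoid
    contamination from grass lodging across subplot borders.
    """

    origin_xy: tuple[float, float]
    plot_side: float
    n_per_side: int
    subplot_side: float
    crop_side: float

    @property
    def n_subplots(self) -> int:
        return self.n_per_side ** 2

    @property
    def extent(self) -> tuple[float, float, float, float]:
        x0, y0 = self.origin_xy
        return (x0, y0, x0 + self.plot_side, y0 + self.plot_side)

    @property
    def area_m2(self) -> float:
        return self.plot_side ** 2

    def subplot_origin(self, idx: int) -> tuple[float, float]:
        i, j = divmod(idx, self.n_per_side)
        x0, y0 = self.origin_xy
        return (x0 + j * self.subplot_side, y0 + i * self.subplot_side)

    def crop_window(self, idx: int) -> tuple[float, float, float, float]:
        """Centered crop window (x0, y0, x1, y1) of one subplot."""
        sx, sy = self.subplot_origin(idx)
        off = (self.subplot_side - self.crop_side) / 2.0
        return (sx + off, sy + off, sx + off + self.crop_side, sy + off + self.crop_side)

    def subplot_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Flat subplot id per coordinate (clipped to the plot)."""
        x0, y0 = self.origin_xy
        j = np.clip(np.floor((np.asarray(x) - x0) / self.subplot_side).astype(np.int64),
                    0, self.n_per_side - 1)
        i = np.clip(np.floor((np.asarray(y) - y0) / self.subplot_side).astype(np.int64),
                    0, self.n_per_side - 1)
        return i * self.n_per_side + j


def make_layout(plot_side: float, n_per_side: int, subplot_side: float,
                crop_side: float, origin_xy: tuple[float, float] = (0.0, 0.0)) -> SubplotLayout:
    """Build the plot/subplot geometry (defaults mirror the 2.5 m study plot)."""
    if plot_side <= 0 or subplot_side <= 0 or crop_side <= 0 or n_per_side < 1:
        raise ValueError("all layout sizes must be positive")
    if crop_side > subplot_side:
        raise ValueError("crop_side must not exceed subplot_side")
    if n_per_side * subplot_side > plot_side + 1e-9:
        raise ValueError("subplot grid does not fit inside the plot")
    return SubplotLayout(origin_xy=origin_xy, plot_side=plot_side,
                         n_per_side=n_per_side, subplot_side=subplot_side,
                         crop_side=crop_side)


# ---------------------------------------------------------------------------
# smooth random fields (ground micro-relief, correlated sensor error)
# ---------------------------------------------------------------------------

class SmoothField:
    """Smooth zero-mean Gaussian random field over a square extent.

    Built by Gaussian-filtering white noise on a node grid (node spacing =
    correlation_length / 3, filter sigma = 3 nodes) and rescaling so the node
    standard deviation equals ``sd`` exactly; queries interpolate linearly
    between nodes.  ``sd = 0`` yields the zero field.
    """

    def __init__(self, extent: tuple[float, float, float, float], sd: float,
                 correlation_length: float, seed, clip_sd: float | None = None):
        if sd < 0:
            raise ValueError("field sd must be non-negative")
        if correlation_length <= 0:
            raise ValueError("correlation_length must be positive")
        self.sd = float(sd)
        self.correlation_length = float(correlation_length)
        self.extent = extent
        x0, y0, x1, y1 = extent
        if sd == 0:
            self._interp = None
            return
        h = correlation_length / 3.0
        pad = 4  # nodes beyond the extent so edge queries are well supported
        nx = int(np.ceil((x1 - x0) / h)) + 1 + 2 * pad
        ny = int(np.ceil((y1 - y0) / h)) + 1 + 2 * pad
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal((ny, nx))
        fld = ndimage.gaussian_filter(noise, sigma=3.0, mode="reflect")
        # normalise moments over the nodes inside the extent, not the padding,
        # so the realised in-extent SD matches the requested one
        core = fld[pad:ny - pad, pad:nx - pad]
        fld -= core.mean()
        fld *= sd / core.std()
        if clip_sd is not None:
            np.clip(fld, -clip_sd * sd, clip_sd * sd, out=fld)
        xs = x0 + (np.arange(nx) - pad) * h
        ys = y0 + (np.arange(ny) - pad) * h
        self._interp = RegularGridInterpolator((ys, xs), fld, method="linear",
                                               bounds_error=False, fill_value=0.0)

    def __call__(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if self._interp is None:
            return np.zeros(np.broadcast(x, y).shape)
        return self._interp(np.stack(np.broadcast_arrays(y, x), axis=-1))


@dataclass
class GroundModel:
    """Almost-flat ground surface: smooth random micro-relief around z = 0.

    ``elevation(x, y)`` is deterministic for a fixed seed, has ~zero mean,
    node-level SD equal to ``relief_sd``, and is clipped to
    +/- ``GROUND_CLIP_SD * relief_sd``.
    """

    relief_sd: float
    correlation_length: float
    seed: int
    _field: SmoothField = field(repr=False, compare=False, default=None)

    def elevation(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self._field(x, y)


def generate_ground(layout: SubplotLayout, relief_sd: float,
                    correlation_length: float, seed) -> GroundModel:
    """Generate the plot's ground micro-relief field."""
    if relief_sd < 0:
        raise ValueError("relief_sd must be non-negative")
    fld = SmoothField(layout.extent, relief_sd, correlation_length, seed,
                      clip_sd=GROUND_CLIP_SD)
    return GroundModel(relief_sd=relief_sd, correlation_length=correlation_length,
                       seed=seed, _field=fld)


# ---------------------------------------------------------------------------
# canopy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeafBlade:
    """One canopy-surface leaf element."""

    base_xy: tuple[float, float]
    tip_height_above_ground: float
    width: float
    azimuth: float


@dataclass
class CanopyScene:
    """Ground + leaf blades + layout, before or after harvest.

    Blade attributes are stored as flat arrays (one entry per blade) for
    vectorised sampling; :meth:`blades` iterates them as :class:`LeafBlade`
    records.  ``tip_height`` is measured above the local ground surface.
    """

    ground: GroundModel
    layout: SubplotLayout
    base_xy: np.ndarray          # (N, 2) m
    tip_height: np.ndarray       # (N,) m above local ground
    width: np.ndarray            # (N,) m
    azimuth: np.ndarray          # (N,) rad
    subplot_idx: np.ndarray      # (N,) flat subplot id
    state: str = PRE_HARVEST
    stubble_height: float | None = None

    @property
    def n_blades(self) -> int:
        return self.base_xy.shape[0]

    def blades(self) -> Iterator[LeafBlade]:
        for k in range(self.n_blades):
            yield LeafBlade(base_xy=tuple(self.base_xy[k]),
                            tip_height_above_ground=float(self.tip_height[k]),
                            width=float(self.width[k]),
                            azimuth=float(self.azimuth[k]))

    def tip_z(self) -> np.ndarray:
        """Absolute tip elevation: local ground + tip height."""
        return self.ground.elevation(self.base_xy[:, 0], self.base_xy[:, 1]) + self.tip_height


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and coefficient of variation."""
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_canopy(ground: GroundModel, layout: SubplotLayout,
                    subplot_mean_heights_mm: Sequence[float], height_cv: float,
                    blades_per_m2: float, leaf_width: float = 0.010,
                    seed=0) -> CanopyScene:
    """Populate the plot with leaf blades with per-subplot height structure.

    Blades are placed uniformly within each subplot; tip heights are drawn
    from a lognormal with the subplot's mean (mm) and common coefficient of
    variation ``height_cv`` (``cv = 0`` gives exactly the mean).  The blade
    count per subplot is ``round(blades_per_m2 * subplot_area)``.
    """
    heights = np.asarray(subplot_mean_heights_mm, dtype=float)
    if heights.shape != (layout.n_subplots,):
        raise ValueError(
            f"need one mean height per subplot ({layout.n_subplots}), got {heights.shape}"
        )
    if np.any(heights <= 0):
        raise ValueError("subplot mean heights must be positive")
    if blades_per_m2 <= 0:
        raise ValueError("blades_per_m2 must be positive")
    if height_cv < 0:
        raise ValueError("height_cv must be non-negative")
    if leaf_width <= 0:
        raise ValueError("leaf_width must be positive")

    rng = np.random.default_rng(seed)
    n_per_subplot = int(round(blades_per_m2 * layout.subplot_side ** 2))
    base, tips, sub = [], [], []
    for idx in range(layout.n_subplots):
        sx, sy = layout.subplot_origin(idx)
        xy = rng.uniform(0.0, layout.subplot_side, size=(n_per_subplot, 2))
        xy[:, 0] += sx
        xy[:, 1] += sy
        mean_m = heights[idx] / 1000.0
        if height_cv == 0:
            h = np.full(n_per_subplot, mean_m)
        else:
            mu, sigma = _lognormal_params(mean_m, height_cv)
            h = rng.lognormal(mu, sigma, size=n_per_subplot)
        base.append(xy)
        tips.append(h)
        sub.append(np.full(n_per_subplot, idx, dtype=np.int64))
    n = n_per_subplot * layout.n_subplots
    return CanopyScene(
        ground=ground,
        layout=layout,
        base_xy=np.concatenate(base, axis=0),
        tip_height=np.concatenate(tips),
        width=np.full(n, leaf_width),
        azimuth=rng.uniform(0.0, 2 * np.pi, size=n),
        subplot_idx=np.concatenate(sub),
        state=PRE_HARVEST,
    )


def harvest(scene: CanopyScene, stubble_height: float = 0.03) -> CanopyScene:
    """Cut every blade to ``stubble_height`` above local ground.

    Returns a new post-harvest scene; ground, layout, blade count, and blade
    base positions are unchanged.  Harvesting an already harvested scene, or
    to a stubble taller than the shortest blade, is rejected.
    """
    if scene.state != PRE_HARVEST:
        raise ValueError("scene is already harvested")
    if stubble_height <= 0:
        raise ValueError("stubble_height must be positive")
    if scene.n_blades and stubble_height >= float(scene.tip_height.min()):
        raise ValueError(
            f"stubble_height {stubble_height} m is not below the shortest blade "
            f"({scene.tip_height.min():.4f} m)"
        )
    return replace(
        scene,
        tip_height=np.full(scene.n_blades, float(stubble_height)),
        state=POST_HARVEST,
        stubble_height=float(stubble_height),
    )


# ---------------------------------------------------------------------------
# ruler truth
# ---------------------------------------------------------------------------

@dataclass
class TruthTable:
    """Per-subplot 'true' grass height (mm) from simulated ruler probing."""

    heights_mm: np.ndarray
    n_probes: int
    seed: int

    def __post_init__(self) -> None:
        self.heights_mm = np.asarray(self.heights_mm, dtype=float)
        if np.any(self.heights_mm < 0):
            raise ValueError("truth heights must be non-negative")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "subplot_id": np.arange(self.heights_mm.size),
            "truth_mm": self.heights_mm,
        })


def ruler_truth(scene: CanopyScene, n_probes: int = 5, seed=0) -> TruthTable:
    """Simulate manual ruler measurement: probe a few blades per subplot.

    Per subplot, ``n_probes`` blades are sampled uniformly without
    replacement (with replacement, plus a warning, if the subplot holds fewer
    blades) and their tip heights above local ground averaged, in mm.
    """
    if scene.state != PRE_HARVEST:
        raise ValueError("ruler truth is measured before harvest")
    if n_probes < 1:
        raise ValueError("n_probes must be at least 1")
    rng = np.random.default_rng(seed)
    out = np.zeros(scene.layout.n_subplots)
    for idx in range(scene.layout.n_subplots):
        tips = scene.tip_height[scene.subplot_idx == idx]
        if tips.size == 0:
            raise ValueError(f"subplot {idx} contains no blades")
        if tips.size < n_probes:
            logger.warning(
                "subplot %d has %d blades < %d probes; sampling with replacement",
                idx, tips.size, n_probes,
            )
            pick = rng.choice(tips.size, size=n_probes, replace=True)
        else:
            pick = rng.choice(tips.size, size=n_probes, replace=False)
        out[idx] = tips[pick].mean() * 1000.0
    return TruthTable(heights_mm=out, n_probes=n_probes, seed=seed)


# ---------------------------------------------------------------------------
# sensors
# ---------------------------------------------------------------------------

@dataclass
class SensorModel:
    """Parameters of one measurement system (SfM photogrammetry or LiDAR).

    Parameters
    ----------
    kind : "sfm" | "lidar"
    name : str
        Tag written into sampled clouds.
    density : float
        Nominal point density, points per cm^2 (sensor specification).
    scale : float
        Global density downscale factor; the realised density is
        ``density * scale``.  Sensor densities keep their ratios.
    vertical_jitter_sd : float
        SD (m) of the spatially correlated vertical error field (wind and
        reconstruction artefacts for SfM; residual drift for LiDAR, applied
        per revisit so averaging shrinks it).
    jitter_correlation_length : float
        Correlation length (m) of that error field.
    point_noise_sd : float
        SD (m) of the small independent per-point vertical noise.
    ground_visible_fraction : float
        SfM only: probability that a sampled location reconstructs the
        ground instead of the canopy envelope (the sward occludes the
        ground; small even after harvest because stubble remains).
    ground_visible_fraction_pre : float | None
        SfM only: override for the pre-harvest epoch (taller canopy occludes
        more).  ``None`` means use ``ground_visible_fraction`` for both.
    depth_sd_mult : float
        Canopy returns sit below the canopy upper envelope by a depth whose
        scale includes ``depth_sd_mult x local tip-height SD``: the sensor
        samples into the canopy-surface height distribution.  Zero for a
        constant-height canopy.  For LiDAR the depth is drawn per beam
        (Exp-distributed — the narrow beam penetrates between leaves); for
        SfM it is a correlated field (see ``depth_jitter_mult``).
    depth_jitter_mult : float
        SfM only: the reconstruction-depth field scale also includes
        ``depth_jitter_mult x vertical_jitter_sd`` — leaf motion, not just
        static tip structure, defeats tip triangulation.  The depth field is
        ``scale x G(x, y)^2`` with G a smooth unit-variance field of
        correlation length ``depth_correlation_length``, so it is
        non-negative, has that mean scale, and touches zero in patches.
    depth_correlation_length : float
        SfM only: correlation length (m) of the reconstruction-depth field.
    footprint_xy : (float, float)
        LiDAR only: beam footprint on the ground (m), bounding the beam's
        effective spatial resolution.
    n_revisits : int
        LiDAR only: evaluations averaged per leaf return (the scanner passes
        over each spot repeatedly).
    lean_factor : float
        LiDAR only: fraction of a blade's length presented as horizontally
        projected area when computing canopy cover inside the footprint.
    ground_noise_sd : float
        LiDAR only: vertical noise SD (m) of ground returns.
    cover_override : float | None
        LiDAR only: if set, use this canopy cover everywhere instead of the
        blade-derived cover (testing hook; 0 forces full ground penetration,
        1 forces all-leaf returns).
    seed : int
        Base seed for the sampler's random streams.
    """

    kind: str
    name: str
    density: float
    scale: float = 1.0
    vertical_jitter_sd: float = 0.0
    jitter_correlation_length: float = 0.15
    point_noise_sd: float = 0.0
    ground_visible_fraction: float = 0.1
    ground_visible_fraction_pre: float | None = None
    depth_sd_mult: float = 0.0
    depth_jitter_mult: float = 0.0
    depth_correlation_length: float = 0.05
    footprint_xy: tuple[float, float] = (0.0318, 0.0200)
    n_revisits: int = 1
    lean_factor: float = 0.3
    ground_noise_sd: float = 0.0
    cover_override: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("sfm", "lidar"):
            raise ValueError("sensor kind must be 'sfm' or 'lidar'")
        if self.density <= 0 or self.scale <= 0:
            raise ValueError("density and scale must be positive")
        if not 0.0 <= self.ground_visible_fraction <= 1.0:
            raise ValueError("ground_visible_fraction must lie in [0, 1]")
        if self.cover_override is not None and not 0.0 <= self.cover_override <= 1.0:
            raise ValueError("cover_override must lie in [0, 1]")
        if self.n_revisits < 1:
            raise ValueError("n_revisits must be at least 1")


#: default density scale: keeps the published sensor density ratios
#: (789 : 269 : 9 points/cm^2) while reducing run time; 0.1 keeps the LiDAR
#: model in its multi-return-per-cell regime at its optimal 20 mm resolution.
DEFAULT_SCALE = 0.1


def uav_sfm_sensor(seed: int = 0, scale: float = DEFAULT_SCALE, **overrides) -> SensorModel:
    """UAV-borne SfM: densest cloud, strongest wind/downdraft error field."""
    kw = dict(kind="sfm", name="uav_sfm", density=789.0, scale=scale,
              vertical_jitter_sd=0.015, point_noise_sd=0.001,
              ground_visible_fraction=0.10, ground_visible_fraction_pre=0.02,
              depth_sd_mult=2.0, depth_jitter_mult=2.0, seed=seed)
    kw.update(overrides)
    return SensorModel(**kw)


def pole_sfm_sensor(seed: int = 0, scale: float = DEFAULT_SCALE, **overrides) -> SensorModel:
    """Pole-camera SfM: no propeller downdraft, so a weaker error field."""
    kw = dict(kind="sfm", name="pole_sfm", density=269.0, scale=scale,
              vertical_jitter_sd=0.008, point_noise_sd=0.001,
              ground_visible_fraction=0.10, ground_visible_fraction_pre=0.02,
              depth_sd_mult=2.0, depth_jitter_mult=2.0, seed=seed)
    kw.update(overrides)
    return SensorModel(**kw)


def lidar_sensor(seed: int = 0, scale: float = DEFAULT_SCALE, **overrides) -> SensorModel:
    """Hand-held LiDAR: sparse, smooth (revisit-averaged), ground-penetrating."""
    kw = dict(kind="lidar", name="lidar", density=9.0, scale=scale,
              vertical_jitter_sd=0.006, point_noise_sd=0.001,
              depth_sd_mult=7.5, footprint_xy=(0.0318, 0.0200), n_revisits=9,
              lean_factor=0.3, ground_noise_sd=0.002, seed=seed)
    kw.update(overrides)
    return SensorModel(**kw)


def default_sensors(seed: int = 0, scale: float = DEFAULT_SCALE) -> dict[str, SensorModel]:
    """The three study sensors with distinct derived seeds."""
    ss = np.random.SeedSequence([int(seed), 901]).generate_state(3)
    return {
        "uav_sfm": uav_sfm_sensor(seed=int(ss[0]) % (2 ** 31), scale=scale),
        "pole_sfm": pole_sfm_sensor(seed=int(ss[1]) % (2 ** 31), scale=scale),
        "lidar": lidar_sensor(seed=int(ss[2]) % (2 ** 31), scale=scale),
    }


# ---------------------------------------------------------------------------
# canopy field summaries used by the samplers
# ---------------------------------------------------------------------------

class _CanopyField:
    """Gridded canopy summaries: upper envelope, cover inputs, tip spread.

    A grid with cell size ``ENVELOPE_RADIUS`` collects per-cell blade
    statistics; 3 x 3 neighbourhood aggregation then approximates "within a
    smoothing radius" queries.  The envelope is the neighbourhood max of
    absolute blade-tip elevation; tip mean/SD and blade areal density are
    neighbourhood moments, used for cover and penetration-depth scales.
    """

    def __init__(self, scene: CanopyScene):
        self.scene = scene
        x0, y0, x1, y1 = scene.layout.extent
        self.cell = ENVELOPE_RADIUS
        self.x0, self.y0 = x0, y0
        self.nx = max(int(np.ceil((x1 - x0) / self.cell)), 1)
        self.ny = max(int(np.ceil((y1 - y0) / self.cell)), 1)
        shape = (self.ny, self.nx)

        if scene.n_blades == 0:
            self.envelope = np.full(shape, np.nan)
            self.density = np.zeros(shape)
            self.tip_mean = np.zeros(shape)
            self.tip_sd = np.zeros(shape)
            return

        bx, by = scene.base_xy[:, 0], scene.base_xy[:, 1]
        col = np.clip(((bx - x0) / self.cell).astype(np.int64), 0, self.nx - 1)
        row = np.clip(((by - y0) / self.cell).astype(np.int64), 0, self.ny - 1)
        flat = row * self.nx + col
        n_cells = self.nx * self.ny

        tip_z = scene.tip_z()
        env = np.full(n_cells, -np.inf)
        np.maximum.at(env, flat, tip_z)
        env = env.reshape(shape)
        env = ndimage.maximum_filter(env, size=3, mode="constant", cval=-np.inf)
        self.envelope = np.where(np.isfinite(env), env, np.nan)

        counts = np.bincount(flat, minlength=n_cells).astype(float)
        s1 = np.bincount(flat, weights=scene.tip_height, minlength=n_cells)
        s2 = np.bincount(flat, weights=scene.tip_height ** 2, minlength=n_cells)
        k = np.ones((3, 3))
        c9 = ndimage.convolve(counts.reshape(shape), k, mode="constant", cval=0.0)
        s19 = ndimage.convolve(s1.reshape(shape), k, mode="constant", cval=0.0)
        s29 = ndimage.convolve(s2.reshape(shape), k, mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(c9 > 0, s19 / np.maximum(c9, 1), 0.0)
            var = np.where(c9 > 1, s29 / np.maximum(c9, 1) - mean ** 2, 0.0)
        # guard against catastrophic cancellation for (near-)constant canopies
        var = np.where(var < 1e-12 * mean ** 2, 0.0, var)
        self.density = c9 / (9.0 * self.cell ** 2)  # blades per m^2, local
        self.tip_mean = mean
        self.tip_sd = np.sqrt(np.maximum(var, 0.0))
        self.mean_width = float(scene.width.mean())

    def _cells(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        col = np.clip(((x - self.x0) / self.cell).astype(np.int64), 0, self.nx - 1)
        row = np.clip(((y - self.y0) / self.cell).astype(np.int64), 0, self.ny - 1)
        return row, col

    def envelope_at(self, x, y) -> np.ndarray:
        r, c = self._cells(np.asarray(x, float), np.asarray(y, float))
        return self.envelope[r, c]

    def tip_sd_at(self, x, y) -> np.ndarray:
        r, c = self._cells(np.asarray(x, float), np.asarray(y, float))
        return self.tip_sd[r, c]

    def cover_at(self, x, y, lean_factor: float) -> np.ndarray:
        """Local canopy cover fraction: 1 - exp(-density * width * length * lean)."""
        r, c = self._cells(np.asarray(x, float), np.asarray(y, float))
        lai = self.density[r, c] * self.mean_width * self.tip_mean[r, c] * lean_factor \
            if self.scene.n_blades else np.zeros(np.shape(x))
        return 1.0 - np.exp(-lai)


def _n_points(sensor: SensorModel, layout: SubplotLayout) -> int:
    area_cm2 = layout.area_m2 * 1e4
    return int(round(sensor.density * sensor.scale * area_cm2))


def _epoch_seed(sensor: SensorModel, scene: CanopyScene, stream: int) -> np.random.SeedSequence:
    epoch_code = 0 if scene.state == PRE_HARVEST else 1
    return np.random.SeedSequence([int(sensor.seed), epoch_code, stream])


def sample_sfm(scene: CanopyScene, sensor: SensorModel) -> PointCloud:
    """Sample a scene with the SfM photogrammetry model.

    Produces ``density * scale * plot_area`` points uniform in (x, y).  Each
    point reconstructs the local canopy surface — the upper envelope minus a
    correlated, non-negative reconstruction-depth field — or, with
    probability ``ground_visible_fraction``, the local ground; both carry
    the correlated vertical error field plus per-point noise.  Locations
    with no canopy in reach always return ground.
    """
    if sensor.kind != "sfm":
        raise ValueError(f"sample_sfm requires an sfm sensor, got kind={sensor.kind!r}")
    layout = scene.layout
    n = _n_points(sensor, layout)
    rng = np.random.default_rng(_epoch_seed(sensor, scene, stream=0))
    x0, y0, x1, y1 = layout.extent
    x = rng.uniform(x0, x1, size=n)
    y = rng.uniform(y0, y1, size=n)

    fld = _CanopyField(scene)
    env = fld.envelope_at(x, y)
    gvf = sensor.ground_visible_fraction
    if scene.state == PRE_HARVEST and sensor.ground_visible_fraction_pre is not None:
        gvf = sensor.ground_visible_fraction_pre
    is_ground = rng.random(n) < gvf
    is_ground |= ~np.isfinite(env)

    jitter = SmoothField(layout.extent, sensor.vertical_jitter_sd,
                         sensor.jitter_correlation_length,
                         _epoch_seed(sensor, scene, stream=1))
    z = np.empty(n)
    ground_z = scene.ground.elevation(x, y)
    z[is_ground] = ground_z[is_ground]
    leaf = ~is_ground
    if leaf.any():
        depth_scale = (sensor.depth_jitter_mult * sensor.vertical_jitter_sd
                       + sensor.depth_sd_mult * fld.tip_sd_at(x[leaf], y[leaf]))
        if np.any(depth_scale > 0):
            g = SmoothField(layout.extent, 1.0, sensor.depth_correlation_length,
                            _epoch_seed(sensor, scene, stream=2))
            depth = depth_scale * g(x[leaf], y[leaf]) ** 2
        else:
            depth = 0.0
        # the reconstructed canopy surface cannot lie below the visible ground
        z[leaf] = np.maximum(env[leaf] - depth, ground_z[leaf])
    z += jitter(x, y)
    if sensor.point_noise_sd > 0:
        z += rng.normal(0.0, sensor.point_noise_sd, size=n)
    return PointCloud(np.column_stack((x, y, z)), sensor_tag=sensor.name,
                      epoch=scene.state)


def sample_lidar(scene: CanopyScene, sensor: SensorModel) -> PointCloud:
    """Sample a scene with the scanning-LiDAR model.

    Each beam hits a leaf with probability equal to the local canopy cover
    inside its footprint, else it passes between the leaves and returns the
    ground.  Leaf returns average ``n_revisits`` evaluations of the envelope
    at footprint-jittered locations (each with the correlated error field
    applied), minus an exponential penetration depth; ground returns carry
    only small vertical noise.
    """
    if sensor.kind != "lidar":
        raise ValueError(f"sample_lidar requires a lidar sensor, got kind={sensor.kind!r}")
    layout = scene.layout
    n = _n_points(sensor, layout)
    rng = np.random.default_rng(_epoch_seed(sensor, scene, stream=0))
    x0, y0, x1, y1 = layout.extent
    x = rng.uniform(x0, x1, size=n)
    y = rng.uniform(y0, y1, size=n)

    fld = _CanopyField(scene)
    if sensor.cover_override is not None:
        cover = np.full(n, float(sensor.cover_override))
    else:
        cover = fld.cover_at(x, y, sensor.lean_factor)
    env = fld.envelope_at(x, y)
    no_canopy = ~np.isfinite(env)
    is_leaf = (rng.random(n) < cover) & ~no_canopy
    frac_ground = 1.0 - is_leaf.mean() if n else 0.0
    logger.info("sample_lidar[%s/%s]: %.1f%% ground returns",
                sensor.name, scene.state, 100 * frac_ground)

    z = np.empty(n)
    ground_z = scene.ground.elevation(x, y)
    gz = ground_z.copy()
    if sensor.ground_noise_sd > 0:
        gz = gz + rng.normal(0.0, sensor.ground_noise_sd, size=n)
    z[~is_leaf] = gz[~is_leaf]

    if is_leaf.any():
        xl, yl = x[is_leaf], y[is_leaf]
        m = xl.size
        fx, fy = sensor.footprint_xy
        noiseless = sensor.vertical_jitter_sd == 0 and fx == 0 and fy == 0
        if sensor.n_revisits == 1 or noiseless:
            zl = env[is_leaf]
            if sensor.vertical_jitter_sd > 0:
                zl = zl + rng.normal(0.0, sensor.vertical_jitter_sd, size=m)
        else:
            acc = np.zeros(m)
            for _ in range(sensor.n_revisits):
                xr = xl + rng.normal(0.0, fx / 4.0, size=m)
                yr = yl + rng.normal(0.0, fy / 4.0, size=m)
                e = fld.envelope_at(xr, yr)
                e = np.where(np.isfinite(e), e, ground_z[is_leaf])
                acc += e + rng.normal(0.0, sensor.vertical_jitter_sd, size=m)
            zl = acc / sensor.n_revisits
        depth_scale = sensor.depth_sd_mult * fld.tip_sd_at(xl, yl)
        depth = np.where(depth_scale > 0,
                         rng.exponential(1.0, size=m) * depth_scale, 0.0)
        # a beam penetrating past the lowest leaf is a ground return
        z[is_leaf] = np.maximum(zl - depth, ground_z[is_leaf])
    if sensor.point_noise_sd > 0:
        z += rng.normal(0.0, sensor.point_noise_sd, size=n)
    return PointCloud(np.column_stack((x, y, z)), sensor_tag=sensor.name,
                      epoch=scene.state)


def sample_cloud(scene: CanopyScene, sensor: SensorModel) -> PointCloud:
    """Dispatch to :func:`sample_sfm` or :func:`sample_lidar` by sensor kind."""
    if sensor.kind == "sfm":
        return sample_sfm(scene, sensor)
    return sample_lidar(scene, sensor)
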
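# Methods

This note documents the models behind `canopyheight`: the estimation
pipeline, the synthetic scene and sensor models, the defaults and why they
were chosen, and what the synthetic validation does and does not show about
real field data.

## Estimation pipeline

Canopy height is estimated as the cellwise difference, in mm, between a
pre-harvest and a post-harvest DSM built on the identical grid (same origin
and cell size, so no resampling is involved). Four selection methods define
which per-cell aggregate enters each epoch: maximum (max/max), average
(mean/mean), minimum (min/min), and maximum−minimum (max/min).

Rasterization conventions:

* cells are half-open intervals `[x0 + j·c, x0 + (j+1)·c)` with the origin
  at the plot's minimum corner; a point on a shared edge belongs to the
  +x/+y cell, so every in-extent point lands in exactly one cell;
* empty cells are masked nodata and are never interpolated — interpolation
  would blur precisely the method-versus-resolution contrast the pipeline
  is built to measure;
* a difference cell is masked if either epoch is masked; negative
  differences are kept (clipping would bias the minimum method differently
  from the others) and only counted in the log;
* an extent that is not a multiple of the cell size is expanded to the next
  multiple (logged), keeping the origin fixed.

Per-subplot estimates are the arithmetic mean of unmasked difference cells
whose *centers* fall inside the subplot's centered 30 cm crop window (the
crop avoids contamination from grass lodging across subplot borders).
Subplots with zero valid cells are flagged and excluded. The residual 3 cm
stubble is *not* added back to the estimate: the raw DSM difference is
compared against ruler height, and the stubble-induced bias of the
maximum/average/minimum methods is left visible in the reports.

Accuracy is summarised as MAE ± SD, where the errors are per-subplot
`|estimate − ruler truth|` in mm, MAE their mean, and SD the *sample*
standard deviation of those absolute errors. Sensors are compared at their
error-minimising (method, cell size) — exact MAE ties resolve toward the
larger cell size, which leaves fewer empty cells — with one-way ANOVA
followed by Tukey's HSD test at α = 0.01 on the per-subplot absolute
errors, plus the Pearson correlation of estimates against truth.

## Synthetic scene

The scene emulates a measured grass plot with known truth:

* **Layout** — a 2.5 m × 2.5 m plot, 5 × 5 subplots of 0.5 m, each with a
  centered 0.3 m comparison window.
* **Ground** — smooth zero-mean micro-relief: Gaussian-filtered white noise
  on a node grid (node spacing = correlation length / 3, filter σ = 3
  nodes), rescaled so the in-extent node SD equals `relief_sd` (default
  5 mm, correlation length 0.5 m) and clipped at ±4 SD ("almost flat").
  Zero `relief_sd` yields an exactly flat plot.
* **Canopy** — leaf-blade elements placed uniformly within each subplot
  (default 8,000 blades/m², 10 mm wide). Tip heights above local ground are
  lognormal per subplot with the subplot's mean and a common CV. Default
  subplot means are drawn uniformly from 300–500 mm per plot, giving the
  estimate–truth correlation spread to work with. `cv = 0` produces exactly
  the mean (used by the analytic tests).
* **Harvest** — every blade is cut to the stubble height (default 30 mm)
  above local ground; blade count and base positions are conserved.
* **Ruler truth** — per subplot, 5 blades are probed uniformly at random
  and their tip heights averaged (mm), mimicking the manual protocol.

**Why the tip-height CV defaults to 0.01.** Ruler truth is defined as the
*mean* of probed blade tips, while every DSM estimator reads the local
*maximum* surface. The blades therefore represent the visible
canopy-surface elements of a dense, uniform sward — not every understory
leaf — and their within-subplot spread is kept small (≈4 mm at a 400 mm
sward) so that the two height definitions coincide. With a large CV the
cell-max of the canopy envelope rises systematically above the mean-tip
truth, which both misrepresents what a ruler reads on a closed sward and
distorts the method comparison (the inflated envelope partially cancels the
maximum method's stubble bias).

## Sensor models

Both samplers draw `density × scale × plot_area` uniformly distributed
(x, y) measurement locations and decide per point whether the return comes
from the canopy or the ground. Canopy geometry is summarised on a 25 mm
grid: the *upper envelope* (neighbourhood max of absolute tip elevation
within the 25 mm smoothing radius), the local blade density, and the local
tip mean/SD.

**SfM (UAV and pole camera).** A point reconstructs the canopy surface
with probability `1 − ground_visible_fraction`, else the ground (the sward
occludes the ground; defaults 0.02 pre-harvest, 0.10 post-harvest — taller
canopy occludes more). The reconstructed surface is the envelope minus a
*correlated, non-negative reconstruction-depth field*: photogrammetry
cannot triangulate individual swaying leaf tips, so the surface dips below
the envelope, touching it only in patches. The depth field is
`(2·jitter_sd + 2·tip_sd_local) · G(x, y)²` with G a smooth unit-variance
field of 50 mm correlation length, clamped so the surface never lies below
the ground. This reproduces the resolution behaviour of SfM: a coarse DSM
cell usually contains a patch where the depth vanishes, so its maximum
recovers the true envelope, while a fine cell underestimates the tips. A
per-point iid depth would not — at SfM densities the cell maximum would
average it away. All SfM points additionally carry a correlated vertical
error field (wind and motion artefacts; SD 15 mm UAV, 8 mm pole,
correlation length 0.15 m, independently realised per epoch) plus 1 mm iid
per-point noise. The iid term is kept small deliberately: per-cell maxima
over thousands of points would otherwise inflate by ~3σ and corrupt the
method comparison.

**LiDAR.** Each beam hits a leaf with probability equal to the local
canopy cover `1 − exp(−ρ·w·h̄·λ)` (blade density ρ, width w, mean tip
height h̄, lean factor λ = 0.3), else it passes between the leaves and
returns the ground (2 mm noise). Leaf returns average 9 revisits of the
envelope at footprint-jittered locations (footprint 31.8 × 20.0 mm) with
6 mm vertical noise per revisit — the scanner measures each spot many
times, smoothing the surface to an effective ~2 mm — minus a per-beam
exponential penetration depth of scale `7.5 × tip_sd_local`, clamped at
the ground (a beam penetrating past the lowest leaf is a ground return).
Post-harvest stubble cover is low (~0.5 at the defaults), so roughly half
the beams reach the ground — the mechanism that lets the
maximum−minimum rule difference canopy top against true ground.

**Density scale.** Sensor densities default to the published ratio
789 : 269 : 9 points/cm² (UAV-SfM : pole-SfM : LiDAR) multiplied by a
global `scale` factor, default **0.1**. The scale keeps desk-scale runtimes
while preserving the density ratios; it is not pushed lower by default
because the method contrast depends on the *per-cell return count*, not
only on relative density: at scale 0.01 the LiDAR model has ~0.4 returns
per cell at its optimal 20 mm resolution, so nearly every valid cell holds
a single return and all four selection rules collapse to the same value.
At scale 0.1 the LiDAR model keeps ~3.6 returns per 20 mm cell — the
multi-return regime in which min/mean/max differ.

All generators and samplers are deterministic for a fixed seed; random
streams are split per subsystem (ground / canopy / truth / each sensor and
epoch), so changing one does not perturb the others.

## What the replicate study shows

`replicate_experiment` (and `scripts/acceptance.py`) runs 5 independent
plots under the defaults and compares configurations on the
*replicate-mean* MAE; single-replicate reversals are possible and
tolerated. Under these conditions the pipeline reproduces the qualitative
findings the estimator design predicts: the maximum−minimum rule attains
the lowest MAE for every sensor; the LiDAR model beats both SfM models at
their respective best settings (≈5 mm vs ≈10/≈17 mm MAE); LiDAR accuracy
peaks at 20 mm cells and degrades toward both 5 mm (sparse cells, beam
penetration into the canopy) and 100 mm (the cell max rides up on canopy
extremes); and the average rule is nearly flat in resolution, since cell
means are insensitive to binning.

These are statements about the *models*. The simulator emulates surface
geometry, occlusion, penetration, revisit smoothing, and correlated
reconstruction error, but not photogrammetric matching itself, radiometry,
wind dynamics over time, species-specific canopy structure, or
georeferencing error. Passing tests show the pipeline's arithmetic is
right and that the models' mechanisms produce the expected orderings — not
that a particular field campaign would yield these exact numbers.

## Numerical choices

* Heights are metres internally; mm only at reporting boundaries.
* Per-cell aggregation sorts points by flat cell index once and uses
  `reduceat` for min/mean/max simultaneously — exactly equal (not just
  close) to the per-point brute-force loop, which the tests assert.
* The envelope/cover grids use 3 × 3 neighbourhood aggregation on a 25 mm
  grid as the "within a smoothing radius" approximation.
* Neighbourhood tip variance is clamped to zero below a 1e-12 relative
  threshold: catastrophic cancellation on constant canopies would otherwise
  leak a ~1e-9 m spurious penetration depth into the noiseless tests.
* LAS output uses a 0.1 mm coordinate scale (LAS 1.2, point format 0); PLY
  uses double precision, so PLY round-trips are bit-exact.
* Degenerate statistics inputs follow explicit conventions: all-constant
  ANOVA groups report p = 1 with a warning; zero-variance correlation is
  NaN with a warning.

## Problem sizes

The default study (scale 0.1, five replicates) samples ≈4.9 M points per
UAV-SfM cloud, ≈1.7 M per pole-SfM cloud, and ≈56 k per LiDAR cloud, and
rasterizes each epoch at seven cell sizes; a full replicate study runs in
roughly three minutes on one CPU. The pipeline-determinism and exact
recovery tests run at scale 0.01, where a full pipeline pass takes ~30 s.

## Known limitations

* Post-harvest blade tips are exactly at stubble height; real cutting
  leaves a rough surface, which would raise the post-harvest max/mean
  surfaces slightly.
* Canopy cover is derived from local blade density via a Beer–Lambert
  approximation with a fixed lean factor; no explicit ray–leaf
  intersection is performed.
* The SfM model does not represent matching failures, holes, or doming
  artefacts; its error budget is collapsed into the correlated error and
  depth fields.
* Subplot truth and estimates assume the plot frame is exactly aligned
  between epochs; co-registration error is out of scope.
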
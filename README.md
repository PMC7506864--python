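# canopyheight

Grass canopy height estimation from paired 3D point clouds by DSM
differencing, with a synthetic canopy/sensor simulator for validation.

## The problem

Sward height is a standard indicator of grass growth, traditionally measured
by hand with a ruler at a few spots per plot — accurate but slow and sparse.
Proximal remote sensing offers dense alternatives: UAV or pole-camera
photogrammetry (structure from motion, SfM) and portable scanning LiDAR both
deliver 3D point clouds of the sward surface. Turning two such clouds — one
captured before harvest and one after cutting to a known stubble — into a
height map requires two design choices that strongly affect accuracy:

1. **The per-cell selection rule.** Each cloud is gridded into a digital
   surface model (DSM) where a cell of size *c* stores one height selected
   from the points inside it. With per-cell aggregates
   `max`, `mean`, `min`, four estimators of canopy height *h* arise from the
   cellwise difference of the before (b) and after (a) DSMs:

   | method            | before | after | estimate                      |
   |-------------------|--------|-------|-------------------------------|
   | maximum           | max    | max   | `h = max_b − max_a`           |
   | average           | mean   | mean  | `h = mean_b − mean_a`         |
   | minimum           | min    | min   | `h = min_b − min_a`           |
   | maximum−minimum   | max    | min   | `h = max_b − min_a`           |

   The maximum−minimum rule differences the canopy-top surface against the
   lowest post-harvest returns — ideally the ground reached through gaps in
   the stubble — and is therefore the closest to true leaf-tip-to-ground
   height.

2. **The DSM resolution.** Too fine, and cells contain too few (or no)
   points to capture the leaf-tip or ground surface; too coarse, and the
   cell maximum rides up on the canopy's height extremes. The accuracy
   optimum is sensor dependent.

This package implements the full pipeline — rasterization, the four
estimators, per-subplot summaries over centered crop windows, and a
method × resolution × sensor error sweep with one-way ANOVA + Tukey HSD
comparisons — plus a synthetic scene generator with sensor models for
UAV-SfM, pole-camera SfM, and hand-held LiDAR, so every stage is testable
against known truth. The rasterize/estimate stages work equally on external
clouds (CSV, binary PLY, LAS 1.2).

The simulated study conditions: an almost flat 2.5 m × 2.5 m plot split
into 25 subplots of 0.5 m, leaves 10 mm wide, harvest to 3 cm stubble,
sensor densities in the ratio 789 : 269 : 9 points/cm² (UAV-SfM :
pole-SfM : LiDAR), ruler truth as the mean of 5 probed blades per subplot,
DSM cell sizes 5–100 mm, and comparison restricted to the central
30 cm × 30 cm of each subplot. See `docs/methods.md` for the model details
and defaults.

## Worked example

Run the full simulated study (generate plot → sample sensors before/after
harvest → sweep methods × resolutions → compare sensors):

```sh
$ printf 'seed: 7\noutput: {write_clouds: false}\n' > run.yaml
$ canopyheight all --config run.yaml --out demo
  sensor          method  cell_size_mm    mae_mm     sd_mm  pearson_r
   lidar maximum_minimum          20.0  5.861737  2.113322   0.999294
pole_sfm maximum_minimum          40.0  9.764720  8.808303   0.976566
 uav_sfm maximum_minimum          50.0 16.998506 11.904983   0.944971
artifacts written to demo
```

Each row is one sensor's most accurate configuration: for every sensor the
maximum−minimum selection rule wins, the LiDAR model attains the lowest
mean absolute error (MAE ± SD of per-subplot absolute errors, in mm) at a
20 mm cell size with an interior optimum (its error rises at both 5 mm and
100 mm), and the SfM models do best at coarser 40–50 mm cells with roughly
2–3× the LiDAR error. `pearson_r` is the correlation between estimated and
ruler-measured subplot heights. `demo/` contains the full sweep tables
(`sweep_detail.csv`, `sweep_summary.csv`), the comparison report with
Tukey-adjusted p-values (`comparison.json`), and the run log.

Library use mirrors the CLI:

```python
import canopyheight as ch

pre, post, truth = ch.simulate_plot(seed=7)
sensor = ch.lidar_sensor(seed=1)
clouds = {"lidar": (ch.sample_cloud(pre, sensor), ch.sample_cloud(post, sensor))}
table = ch.sweep(clouds, pre.layout, truth)         # 4 methods x 7 cell sizes
grid = ch.make_grid(pre.layout.extent, 0.02)
dsm_b = ch.rasterize(clouds["lidar"][0], grid, "max")
dsm_a = ch.rasterize(clouds["lidar"][1], grid, "min")
height = ch.estimate_height(dsm_b, dsm_a, ch.METHODS["maximum_minimum"])
```

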
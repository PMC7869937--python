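# Methods

This note documents the models, conventions and numerical choices behind
`rugosa`, and what the synthetic-data experiments do and do not demonstrate.

## Pipeline model

The input is a colored point cloud of a crop field reconstructed from nadir
UAS imagery, i.e. an (approximately) single-valued height field with 8-bit
RGB per point, plus a polygon map assigning ground area to experimental
plots. Stages run in a fixed order; each is available separately and through
`rugosa run`.

### Outlier filtering

Two sequential filters, both parameterized by a neighborhood size k = 20 and
a threshold multiplier n_sigma = 3:

1. *Statistical*: the per-point statistic is the mean Euclidean distance to
   the k nearest neighbors; a Gaussian (mu, sigma) is fitted to the
   statistic over the whole cloud and points with statistic > mu + 3 sigma
   are removed. This is the classic PCL-style statistical outlier removal.
2. *Local plane*: a total-least-squares plane (smallest principal direction
   of the neighborhood covariance) is fitted to each point's k nearest
   neighbors, the query excluded; the point's orthogonal distance feeds the
   same cloud-wide mu + 3 sigma rule. Collinear neighborhoods leave the
   distance undefined; such points are retained and counted.

The threshold is one-sided: small distances indicate agreement with the
surface, not anomaly. Both standard deviations use ddof = 1; with zero
variance (perfectly regular spacing) nothing is removed because the
comparison is strict.

A caveat the tests make explicit: the mu + 3 sigma rule only behaves like a
"0.1% false-positive" Gaussian test when the statistic's distribution is
light-tailed. On unstructured clouds (an isotropic Gaussian blob) the
point-to-plane distances are heavier-tailed and 1.5–3% of clean points fall
beyond the threshold. On clean smooth surfaces the distributions are bounded
and false removal is well below 1%, while gross (10-sigma) displaced points
are removed with recall 1.0 — the regime the filters are designed for.

Absolute elevation is calibrated against surveyed height bars: the cloud is
shifted in z by the mean of (surveyed − cloud) elevations over the bars; the
per-bar residuals after the shift are reported. Bar elevations are read from
a CSV; bars are located manually, not auto-detected.

### Regularization

SfM density varies with texture and view overlap, which would bias any
density-sensitive surface statistic. The cloud is therefore rebuilt at a
uniform density:

1. **Mesh** — Delaunay triangulation of the (x, y) projection lifted to z.
   A nadir canopy is treated as a 2.5-D height field; a true 3-D Delaunay
   would produce tetrahedra, not a surface. With `max_edge = None` the
   triangulation covers the convex hull. The pipeline instead sets
   `mesh_max_edge = 0.25 m` and drops every triangle with a longer 3-D edge:
   a hull-covering triangulation bridges genuine coverage gaps and builds
   near-vertical canopy-to-ground "walls" whose resampled points carry
   color-interpolated radiometry and can fuse adjacent rows. 0.25 m is well
   above the point spacing of any realistic dense cloud (≤ 0.06 m at
   300 points/m²) and well below the 0.31 m clear gap between row canopies,
   so only walls and gap bridges are pruned.
2. **Hole repair** — interior boundary loops with perimeter
   ≤ `max_hole_perimeter` (default 0.5 m, small enough never to bridge the
   0.76 m row spacing) are filled by ear-clipping triangulation in the
   loop's best-fit plane. The outer boundary and non-manifold loops are left
   alone; vertex positions never change.
3. **Laplacian smoothing** — each non-boundary vertex moves to the centroid
   of all mesh vertices within a 0.10 m Euclidean radius (1 iteration by
   default). Boundary vertices stay fixed; an optional vertex mask restricts
   smoothing to selected locations. Coplanar neighborhoods have coplanar
   centroids, so flat surfaces stay flat.
4. **Resampling** — round(500 points/m² × surface area) points drawn
   triangle-area-weighted with barycentric position and color interpolation,
   seeded.
5. **Poisson-disk thinning** — dart throwing with culling: points are
   visited in a seeded random order and accepted iff no previously accepted
   point lies within 1 cm. The output is maximal (every rejected point is
   within 1 cm of an accepted one) and its minimum pairwise spacing is
   ≥ 1 cm by construction; both properties are brute-force verified in the
   tests.

### Classification and row extraction

Vegetation is separated from soil by a single cut-off on the green channel:
g ≥ 115 (8-bit) is vegetation by default. The cut-off side is configurable
(`veg_lt_cutoff`) because soil radiometry varies between fields. The audit
helper mirrors a manual spot check: a seeded 1000-point sample without
replacement, overall accuracy and Cohen's kappa from the 2×2 confusion
table (delegated to scikit-learn).

Within a clipped plot, points are voxelized on a 0.15 m grid anchored at the
plot's minimum corner (so results are translation-reproducible), occupied
voxels are joined by 26-connectivity (6-connectivity optional) via
`scipy.ndimage.label`, and each point inherits its voxel's component.
Components with fewer than 50 points are discarded as non-rows. Rows are
ordered by their mean coordinate along the cross-row axis (the horizontal
axis along which component centers spread most), and the two extreme rows
are dropped, leaving 6 analyzed rows in the standard 8-row layout.

### Canopy roughness

Point roughness: all other points within a 0.10 m sphere are the neighbors;
with ≥ 3 non-collinear neighbors a TLS plane is fitted to the neighbors
(query excluded — including it would bias the distance toward zero) and the
query's orthogonal distance recorded, else the point is undefined.
Undefined points are excluded from the plot statistic rather than
zero-filled, which would deflate the median in sparse plots.

Plot statistic: CR = IQR × med over the pooled interior-row roughness
values, in m². The product of the two length scales is the unit-consistent
reading of the trait's definition; an IQR/med ratio variant is available
behind a flag for sensitivity analysis. Quantiles use linear interpolation
of order statistics (numpy default, "type 7") — fixed for bit
reproducibility; at least 4 defined values are required.

### Regression

Five univariate families relate CR (x) to AGB (y): linear, power a·x^b,
exponential a·e^(bx), quadratic polynomial, logarithmic a·ln x + b.
Linear/polynomial/logarithmic are ordinary least squares; power and
exponential are fitted by log-linearization and back-transformation — the
deterministic spreadsheet-trendline convention, bit-reproducible and
consistent with how such models are reported in field studies. Domain
violations (x ≤ 0 for power/log, y ≤ 0 for power/exponential) raise errors
naming the offending plots.

Evaluation is leave-one-out: plot i is predicted by a model fitted to the
other n−1 plots. Over the out-of-fold predictions we report RMSE,
RRMSE = 100·RMSE/ȳ, ASE = (100/n)·Σ(ŷᵢ−yᵢ)/yᵢ (signed, so it measures
systematic bias) and MPSE = (100/n)·Σ|ŷᵢ−yᵢ|/yᵢ; MPSE ≥ |ASE| always. The
headline R² is the squared Pearson correlation of out-of-fold predictions
vs observations (matching 1:1 validation scatter plots); the 1 − SSE/SST
variant is also emitted. Before the final fit, plots with
|residual| / sd(residuals) > 2 are removed and the model refitted,
iterating until the bound holds everywhere; the loop invariant (max
|standardized residual| ≤ 2 after return) is asserted in the tests.
Per-genotype error tables recompute the four metrics over each genotype's
out-of-fold predictions, omitting genotypes with fewer than 3 plots.

## Synthetic fields

The generator emulates the acquisition this pipeline targets, with known
ground truth per point (class label, row id, plot id) and per plot
(surface-irregularity amplitude, genotype, simulated AGB):

- flat soil plane (z ≈ 0) with brownish radiometry, green channel in
  [60, 110]; soil is sampled only where not occluded by canopy, as a nadir
  reconstruction would see it;
- per plot, 8 rows at 0.76 m spacing with a 0.45 m canopy footprint,
  canopy height 0.60 m (full-flowering soybean scale), row length 3 m by
  default (test and acceptance runs use 1.5–2 m rows to keep problem sizes
  small; the geometry is otherwise identical);
- the canopy surface is z = h + a·sin(2πx/λ)·sin(2πy/λ) + N(0, 0.005²) with
  wavelength λ = 0.4 m — a separable sinusoid whose amplitude a is the
  roughness driver, chosen so that the 0.10 m fitting sphere sees genuine
  curvature; a is set per genotype (18 labels, amplitudes spanning
  0.01–0.08 m) with ±10% plot-level variation, making roughness heritable
  in the simulated trial;
- vegetation green channel in [150, 220] — disjoint from soil across the
  115 cut-off, so classification accuracy against truth is exactly 1 in the
  noise-free setting;
- base density 800 points/m² by default (dense-cloud scale), sparse gross
  outliers thrown uniformly into an inflated bounding box, and circular
  dropout holes carved until ~5% of points are removed;
- simulated AGB per plot is model(CR) + N(0, noise_sd²) truncated at zero,
  with a calibration helper that maps the realized CR range onto a
  realistic soybean biomass scale (mean ≈ 150 g/m², sd ≈ 42 g/m²).

One seed sequence is spawned per plot, so regenerating a subset of plots
reproduces them exactly.

What the generator does *not* emulate: real SfM correlated noise and
doming, shadows and mixed pixels at canopy edges, lodging, weeds, within-row
plant gaps from emergence failure, or terrain slope (the ground is flat by
default). Passing tests therefore demonstrate the correctness and internal
consistency of the algorithms — oracle equivalence, invariances, monotone
trait response, parameter recovery — not field-level predictive accuracy;
published R² values from real trials cannot be reproduced from synthetic
data and are not targeted.

## Numerical choices and degenerate inputs

- Collinearity of a neighborhood is declared when the second covariance
  eigenvalue is ≤ 1e-12 × max(largest eigenvalue, 1).
- Boundary points count as inside a plot polygon (closed-polygon
  convention, `shapely.covers`), matching common clipping tools.
- LAS coordinates are stored at 1 mm scale with the offset at the cloud
  minimum; 8-bit colors are stored as c·257 in the 16-bit channels, so
  round-trips are exact for color and ≤ 0.5 mm for coordinates.
- PLY is written with float64 coordinates so write/read round-trips are
  bitwise exact.
- Voxel origins are anchored at each plot's minimum corner; translating a
  plot by any multiple of the grid step yields identical components.
- All stochastic operations (surface sampling, Poisson thinning, the
  generator, audits) take explicit integer seeds recorded in the run log;
  identical config + inputs produce bit-identical output files.
- Ties in Poisson-disk acceptance are resolved by the seeded visiting
  order; output preserves input point order.

## Known limitations

- The 2.5-D meshing assumption fails for multi-layer canopies or strongly
  overhanging vegetation; only the top surface is modeled.
- Log-linearized power/exponential fits minimize error in log space, not in
  the original units; with large relative noise at small y they are biased
  relative to iterative nonlinear least squares (the tests account for the
  induced heteroskedasticity with sandwich standard errors).
- Row extraction assumes row gaps wider than twice the voxel step
  (0.76 m spacing with ≤ 0.45 m canopy satisfies this); fully closed
  canopies will merge rows.
- The height-bar calibration corrects a uniform vertical offset only, not
  tilt or dome distortion.
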
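# rugosa

Canopy roughness from colored 3-D point clouds, and cross-validated
aboveground-biomass estimation — a toolkit for UAS-based high-throughput
crop phenotyping.

## The problem

Breeders need plot-level biomass estimates for hundreds of field plots
without destructive sampling. Dense 3-D point clouds reconstructed from
UAS RGB imagery (structure from motion) capture the canopy surface of every
plot; what is missing is a trait that summarizes that surface and tracks
aboveground biomass (AGB, g/m²). `rugosa` implements such a trait — **canopy
roughness** — together with the full processing chain around it: outlier
filtering, height calibration, point-density regularization,
vegetation/soil classification, plot and row extraction, and univariate
regression of AGB on the trait with leave-one-out cross-validation (LOOCV).

## The trait

For every point *p* in a plot, the **point roughness** r(p) is the Euclidean
distance (m) between *p* and the total-least-squares plane fitted to the
other points inside a sphere of radius 0.10 m around *p*. The plot-level
**canopy roughness** is

```
CR = IQR × med      [m²]
```

where `med` is the median and `IQR` the interquartile range of the point
roughness values of all points in the plot (interior rows only; the two
border rows are dropped to avoid edge effects). A plot is "rough" when
typical surface deviations are both large and widely dispersed.

AGB is then estimated per plot from CR by one of five trendline families
(linear, power, exponential, quadratic polynomial, logarithmic), evaluated
out-of-fold by LOOCV with four error statistics: RMSE (g/m²),
RRMSE = 100·RMSE/ȳ, the signed mean relative error ASE, and the mean
absolute relative error MPSE (all %). Plots with |standardized residual| > 2
are rejected iteratively before the final fit.

Because real trial data are not redistributable, the package ships a
first-class synthetic field generator (`rugosa.synth`) that emulates the
acquisition: 8 plant rows per plot at 0.76 m spacing, genotype-dependent
canopy surface irregularity, disjoint vegetation/soil green-band radiometry,
variable point density with dropout holes, and sparse gross outliers — all
with per-point ground-truth labels.

## Worked example

```
$ rugosa simulate --n-plots 8 --seed 11 --out demo
wrote 111291 points, 8 plots to demo
$ rugosa segment demo/field.ply --out-veg demo/veg.ply
vegetation 65872, soil 45419
$ rugosa roughness demo/veg.ply --plot-map demo/plot_map.csv --out demo/traits.csv
wrote 8 plot traits to demo/traits.csv
$ head -3 demo/traits.csv
plot_id,genotype,n_points,n_undefined,med_m,iqr_m,cr_m2,agb_g_m2
P001,G01,6098,1,0.003866263802983487,0.004781987185625972,1.8488423962116573e-05,
P002,G02,5954,2,0.004170141121011164,0.00523677518933035,2.183809155851752e-05,
```

Each row is one plot: the median (`med_m`) and spread (`iqr_m`) of its point
roughness in meters and their product `cr_m2`, the canopy roughness. After
joining the simulated biomass (`demo/agb.csv`):

```
$ rugosa regress demo/traits_agb.csv --family linear --out demo/model.json
linear: R2=0.838 RMSE=15.25 g/m2 (0 outlier plots removed)
```

i.e. on this small simulated trial the linear CR→AGB model explains 84% of
the out-of-fold biomass variance with a 15 g/m² cross-validated RMSE
(about 10% of the mean plot biomass). `rugosa run` executes the whole chain
(filtering → regularization → classification → traits → regression) from a
YAML config and writes a JSON run log that fully captures parameters and
seeds.

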
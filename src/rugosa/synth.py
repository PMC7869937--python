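"""Synthetic UAS-like canopy fields with known ground truth.

Replaces the flight + SfM acquisition for testing and calibration: a flat
soil plane with brownish radiometry, plots of 8 parallel plant rows at
0.76 m spacing, a genotype-dependent sinusoidal canopy-surface irregularity
(the roughness driver), disjoint green-band color ranges for vegetation and
soil, variable point density with circular dropout holes, and sparse gross
outliers. Every generated point carries a class label, a row id and a plot
id, so each pipeline stage can be checked against the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cloud import ColoredPointCloud
from .io import PlotMap, PlotPolygon
from .regression import ModelSpec, predict

__all__ = ["FieldSpec", "GroundTruth", "generate_field", "simulate_agb",
           "calibrate_agb_model"]


@dataclass
class FieldSpec:
    """Generator configuration; defaults mirror the emulated field trial."""

    n_plots: int = 108
    rows_per_plot: int = 8
    row_spacing: float = 0.76          # m between row centers
    row_length: float = 3.0            # m along the row
    canopy_width: float = 0.45         # m canopy footprint per row
    canopy_height: float = 0.60        # m, full-flowering soybean canopy
    amplitude_range: tuple[float, float] = (0.01, 0.08)  # m, per-genotype
    bump_amplitude: dict[str, float] | None = None  # per-plot override, m
    bump_wavelength: float = 0.40      # m; near the 0.10 m fit radius scale
    base_density: float = 800.0        # points/m^2, SfM-dense-cloud scale
    veg_green_range: tuple[int, int] = (150, 220)
    soil_green_range: tuple[int, int] = (60, 110)
    n_outliers: int = 100
    dropout_fraction: float = 0.05
    jitter_sd: float = 0.005           # m residual SfM surface noise
    alley: float = 1.0                 # m spacing between plot footprints
    n_genotypes: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.row_spacing <= 0 or self.base_density <= 0:
            raise ValueError("row_spacing and base_density must be positive")
        for lo, hi in (self.veg_green_range, self.soil_green_range):
            if not (0 <= lo <= hi <= 255):
                raise ValueError("green ranges must be ordered 8-bit intervals")
        if not 0 <= self.dropout_fraction < 1:
            raise ValueError("dropout_fraction must be in [0, 1)")
        if min(self.amplitude_range) < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.alley <= 0.1:  # plot polygons carry a 0.05 m margin each side
            raise ValueError("alley too small: plot footprints would overlap")


@dataclass
class GroundTruth:
    """Per-point and per-plot truth aligned with the generated cloud."""

    labels: np.ndarray        # 'vegetation' | 'soil' | 'outlier'
    row_id: np.ndarray        # within-plot row index, -1 for non-vegetation
    plot_id: np.ndarray       # plot id per point, '' outside plots
    plot_amplitude: dict[str, float]
    plot_genotype: dict[str, str]
    agb: dict[str, float] = field(default_factory=dict)

    @property
    def vegetation_mask(self) -> np.ndarray:
        return self.labels == "vegetation"


def _plot_origin(index: int, spec: FieldSpec, n_cols: int
                 ) -> tuple[float, float]:
    width = spec.rows_per_plot * spec.row_spacing
    col, row = index % n_cols, index // n_cols
    return (col * (width + spec.alley), row * (spec.row_length + spec.alley))


def generate_field(spec: FieldSpec
                   ) -> tuple[ColoredPointCloud, PlotMap, GroundTruth]:
    """Generate one field: colored cloud, plot polygons and ground truth.

    Vegetation points sit on per-row ridge surfaces
    ``z = h + a * sin(2*pi*x/lam) * sin(2*pi*y/lam) + jitter`` with the
    amplitude ``a`` set per plot through its genotype; soil points sit near
    z = 0; outliers are thrown uniformly into an inflated bounding box; and
    dropout carves random circular holes. Bitwise reproducible per seed.
    """
    root = np.random.SeedSequence(spec.seed)
    plot_streams = [np.random.default_rng(s) for s in root.spawn(spec.n_plots)]
    aux = np.random.default_rng(root.spawn(1)[0])

    genotypes = [f"G{i + 1:02d}" for i in range(spec.n_genotypes)]
    lo, hi = spec.amplitude_range
    geno_amp = {g: lo + (hi - lo) * i / max(1, spec.n_genotypes - 1)
                for i, g in enumerate(genotypes)}

    n_cols = max(1, int(np.ceil(np.sqrt(spec.n_plots))))
    width = spec.rows_per_plot * spec.row_spacing
    lam = spec.bump_wavelength

    xyz_parts, rgb_parts, label_parts, row_parts, plot_parts = [], [], [], [], []
    polygons: list[PlotPolygon] = []
    plot_amplitude: dict[str, float] = {}
    plot_genotype: dict[str, str] = {}

    for p in range(spec.n_plots):
        rng = plot_streams[p]
        plot_id = f"P{p + 1:03d}"
        genotype = genotypes[p % spec.n_genotypes]
        if spec.bump_amplitude and plot_id in spec.bump_amplitude:
            amp = float(spec.bump_amplitude[plot_id])
        else:
            amp = geno_amp[genotype] * float(rng.uniform(0.9, 1.1))
        plot_amplitude[plot_id] = amp
        plot_genotype[plot_id] = genotype
        x0, y0 = _plot_origin(p, spec, n_cols)

        # soil carpet over the plot footprint; points under a canopy strip are
        # dropped (nadir SfM reconstructs only the visible top surface)
        n_soil = rng.poisson(spec.base_density * width * spec.row_length)
        sx = rng.uniform(x0, x0 + width, n_soil)
        sy = rng.uniform(y0, y0 + spec.row_length, n_soil)
        sz = rng.normal(0.0, 0.003, n_soil)
        offset = (sx - x0) % spec.row_spacing - spec.row_spacing / 2
        visible = np.abs(offset) > spec.canopy_width / 2
        sx, sy, sz = sx[visible], sy[visible], sz[visible]
        n_soil = len(sx)
        soil_rgb = np.column_stack([
            rng.integers(120, 181, n_soil),
            rng.integers(spec.soil_green_range[0], spec.soil_green_range[1] + 1,
                         n_soil),
            rng.integers(60, 121, n_soil)])
        xyz_parts.append(np.column_stack([sx, sy, sz]))
        rgb_parts.append(soil_rgb)
        label_parts.append(np.full(n_soil, "soil"))
        row_parts.append(np.full(n_soil, -1))
        plot_parts.append(np.full(n_soil, plot_id, dtype=object))

        # vegetation ridges, one per row
        for r in range(spec.rows_per_plot):
            cx = x0 + (r + 0.5) * spec.row_spacing
            n_veg = rng.poisson(spec.base_density * spec.canopy_width
                                * spec.row_length)
            vx = rng.uniform(cx - spec.canopy_width / 2,
                             cx + spec.canopy_width / 2, n_veg)
            vy = rng.uniform(y0, y0 + spec.row_length, n_veg)
            vz = (spec.canopy_height
                  + amp * np.sin(2 * np.pi * vx / lam)
                        * np.sin(2 * np.pi * vy / lam)
                  + rng.normal(0.0, spec.jitter_sd, n_veg))
            veg_rgb = np.column_stack([
                rng.integers(40, 111, n_veg),
                rng.integers(spec.veg_green_range[0], spec.veg_green_range[1] + 1,
                             n_veg),
                rng.integers(30, 91, n_veg)])
            xyz_parts.append(np.column_stack([vx, vy, vz]))
            rgb_parts.append(veg_rgb)
            label_parts.append(np.full(n_veg, "vegetation"))
            row_parts.append(np.full(n_veg, r))
            plot_parts.append(np.full(n_veg, plot_id, dtype=object))

        margin = 0.05
        polygons.append(PlotPolygon(
            plot_id=plot_id,
            vertices=np.array([
                [x0 - margin, y0 - margin],
                [x0 + width + margin, y0 - margin],
                [x0 + width + margin, y0 + spec.row_length + margin],
                [x0 - margin, y0 + spec.row_length + margin]]),
            genotype=genotype))

    xyz = np.vstack(xyz_parts)
    rgb = np.vstack(rgb_parts).astype(np.uint8)
    labels = np.concatenate(label_parts)
    rows = np.concatenate(row_parts).astype(np.int64)
    plots = np.concatenate(plot_parts).astype(object)

    # circular dropout holes (emulates SfM coverage gaps)
    if spec.dropout_fraction > 0 and len(xyz):
        target = int(spec.dropout_fraction * len(xyz))
        keep = np.ones(len(xyz), dtype=bool)
        lo_xy, hi_xy = xyz[:, :2].min(axis=0), xyz[:, :2].max(axis=0)
        removed, attempts = 0, 0
        while removed < target and attempts < 200:
            attempts += 1
            c = aux.uniform(lo_xy, hi_xy)
            radius = aux.uniform(0.10, 0.35)
            hit = keep & (np.sum((xyz[:, :2] - c) ** 2, axis=1) < radius ** 2)
            removed += int(hit.sum())
            keep[hit] = False
        xyz, rgb = xyz[keep], rgb[keep]
        labels, rows, plots = labels[keep], rows[keep], plots[keep]

    # sparse gross outliers in an inflated bounding box
    if spec.n_outliers > 0:
        lo3, hi3 = xyz.min(axis=0), xyz.max(axis=0)
        span = hi3 - lo3
        olo = lo3 - 0.1 * span - np.array([0, 0, 1.0])
        ohi = hi3 + 0.1 * span + np.array([0, 0, 3.0])
        ox = aux.uniform(olo, ohi, size=(spec.n_outliers, 3))
        orgb = aux.integers(0, 256, size=(spec.n_outliers, 3))
        xyz = np.vstack([xyz, ox])
        rgb = np.vstack([rgb, orgb.astype(np.uint8)])
        labels = np.concatenate([labels, np.full(spec.n_outliers, "outlier")])
        rows = np.concatenate([rows, np.full(spec.n_outliers, -1)])
        plots = np.concatenate([plots, np.full(spec.n_outliers, "", dtype=object)])

    perm = aux.permutation(len(xyz))  # interleave stages like a real cloud
    cloud = ColoredPointCloud(xyz[perm], rgb[perm], crs_label="local-meters",
                              provenance="raw")
    truth = GroundTruth(labels=labels[perm], row_id=rows[perm],
                        plot_id=plots[perm].astype(str),
                        plot_amplitude=plot_amplitude,
                        plot_genotype=plot_genotype)
    return cloud, PlotMap(polygons), truth


def calibrate_agb_model(cr: dict[str, float], target_mean: float = 150.3,
                        target_sd: float = 42.3) -> ModelSpec:
    """Linear CR -> AGB map whose image matches a realistic biomass scale.

    Chooses slope/intercept so the simulated plot biomass has roughly the
    given mean and standard deviation (g/m^2, full-flowering soybean scale).
    """
    values = np.asarray(list(cr.values()), dtype=float)
    sd = values.std(ddof=0)
    a = target_sd / sd if sd > 0 else 0.0
    b = target_mean - a * values.mean()
    return ModelSpec("linear", (a, b))


def simulate_agb(truth: GroundTruth, cr: dict[str, float], model: ModelSpec,
                 noise_sd: float = 10.0, seed: int | None = 0
                 ) -> dict[str, float]:
    """Simulated ground-truth biomass per plot: model(CR) + Gaussian noise.

    Values are truncated at zero (biomass cannot be negative). The result is
    also stored on ``truth.agb``.
    """
    rng = np.random.default_rng(seed)
    agb: dict[str, float] = {}
    for plot_id in sorted(cr):
        mean = float(predict(model, np.asarray([cr[plot_id]]))[0])
        value = mean + float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else mean
        agb[plot_id] = max(0.0, value)
    truth.agb = agb
    return agb
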
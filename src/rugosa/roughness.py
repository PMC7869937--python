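"""Point roughness and the plot-level canopy roughness trait.

*Point roughness* is the Euclidean distance (m) between a point and the
total-least-squares plane of its neighbors inside a sphere of a user-defined
radius (0.10 m by default). *Canopy roughness* (CR) summarizes the per-point
roughness distribution of one plot as

    CR = IQR x med        [m^2]

where ``med`` is the median and ``IQR`` the interquartile range of the
roughness values of all points within the plot. The product of the two
length scales makes CR a squared length: a plot is "rough" when typical
point deviations are both large and widely spread.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .cloud import ColoredPointCloud, concatenate
from .io import PlotMap, clip_by_polygon
from .segment import extract_rows, drop_border_rows

__all__ = [
    "RoughnessField", "PlotTrait", "point_roughness", "canopy_roughness",
    "compute_plot_traits",
]

_COLLINEAR_RTOL = 1e-12


@dataclass
class RoughnessField:
    """Per-point roughness values (m) for one plot; NaN marks undefined."""

    plot_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        defined = self.values[~np.isnan(self.values)]
        if defined.size and (defined.min() < 0 or not np.all(np.isfinite(defined))):
            raise ValueError("defined roughness values must be finite and >= 0")

    @property
    def defined(self) -> np.ndarray:
        return self.values[~np.isnan(self.values)]

    @property
    def n_undefined(self) -> int:
        return int(np.isnan(self.values).sum())


@dataclass
class PlotTrait:
    """One plot's canopy roughness paired with its biomass ground truth."""

    plot_id: str
    cr: float            # canopy roughness, m^2
    med: float           # median point roughness, m
    iqr: float           # interquartile range of point roughness, m
    genotype: str = ""
    agb: float | None = None   # measured aboveground biomass, g/m^2
    n_points: int = 0
    n_undefined: int = 0


def point_roughness(cloud: ColoredPointCloud, radius: float = 0.10,
                    plot_id: str = "") -> RoughnessField:
    """Distance from each point to the best-fit plane of its sphere neighbors.

    For each query point all *other* points within ``radius`` are gathered;
    with at least 3 non-collinear neighbors a total-least-squares plane is
    fitted to the neighbors (query excluded, so its own deviation cannot bias
    the fit) and the query's orthogonal distance recorded. Queries with too
    few or collinear neighbors are marked undefined (NaN).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    n = len(cloud)
    values = np.full(n, np.nan)
    if n == 0:
        return RoughnessField(plot_id, values)
    xyz = cloud.xyz
    tree = cKDTree(xyz)
    neighbor_lists = tree.query_ball_point(xyz, r=radius)
    for i, nbrs in enumerate(neighbor_lists):
        nbrs = [j for j in nbrs if j != i]
        if len(nbrs) < 3:
            continue
        pts = xyz[nbrs]
        centroid = pts.mean(axis=0)
        centered = pts - centroid
        cov = centered.T @ centered
        eigvals, eigvecs = np.linalg.eigh(cov)
        if eigvals[1] <= _COLLINEAR_RTOL * max(eigvals[2], 1.0):
            continue  # collinear neighborhood: plane undefined
        values[i] = abs(np.dot(xyz[i] - centroid, eigvecs[:, 0]))
    return RoughnessField(plot_id, values)


def canopy_roughness(field: RoughnessField, genotype: str = "",
                     agb: float | None = None,
                     combine: str = "product") -> PlotTrait:
    """Collapse a roughness field into the plot-level CR trait.

    ``med`` is the sample median and ``IQR = Q3 - Q1`` with
    linear-interpolation quantiles (numpy's default, the common "type 7"
    convention). ``combine='product'`` gives CR = IQR x med in m^2;
    ``combine='ratio'`` (IQR / med) is available for sensitivity analysis.
    Requires at least 4 defined roughness values so quartiles are meaningful.
    """
    defined = field.defined
    if defined.size < 4:
        raise ValueError(
            f"plot {field.plot_id!r}: only {defined.size} defined roughness "
            "values; quartiles need at least 4")
    med = float(np.median(defined))
    q1, q3 = np.percentile(defined, [25.0, 75.0])
    iqr = float(q3 - q1)
    if combine == "product":
        cr = iqr * med
    elif combine == "ratio":
        cr = iqr / med if med > 0 else np.inf
    else:
        raise ValueError(f"unknown combine rule {combine!r}")
    return PlotTrait(plot_id=field.plot_id, cr=cr, med=med, iqr=iqr,
                     genotype=genotype, agb=agb,
                     n_points=int(field.values.size),
                     n_undefined=field.n_undefined)


def compute_plot_traits(field_cloud: ColoredPointCloud, plot_map: PlotMap,
                        *, radius: float = 0.10, grid_step: float = 0.15,
                        min_cluster_size: int = 50, connectivity: int = 26,
                        drop_borders: bool = True, combine: str = "product",
                        ) -> tuple[list[PlotTrait], dict[str, str]]:
    """Per-plot canopy roughness over a (vegetation) field cloud.

    For each plot polygon: clip, split into rows, drop the border rows, pool
    the interior-row points, compute point roughness and collapse it to CR.
    Plots that fail a stage (empty clip, too few rows, too few defined
    roughness values) are reported in the failure map instead of raising.
    """
    traits: list[PlotTrait] = []
    failures: dict[str, str] = {}
    for poly in plot_map:
        plot_cloud = clip_by_polygon(field_cloud, poly)
        if len(plot_cloud) == 0:
            failures[poly.plot_id] = "no points inside plot polygon"
            continue
        rows = extract_rows(plot_cloud, grid_step=grid_step,
                            min_cluster_size=min_cluster_size,
                            connectivity=connectivity)
        if drop_borders:
            if len(rows) < 3:
                failures[poly.plot_id] = (
                    f"only {len(rows)} rows found; cannot drop border rows")
                continue
            rows = drop_border_rows(rows)
        elif not rows:
            failures[poly.plot_id] = "no rows above the cluster-size threshold"
            continue
        pooled = concatenate([r.points for r in rows], provenance="plot")
        rough = point_roughness(pooled, radius=radius, plot_id=poly.plot_id)
        if rough.defined.size < 4:
            failures[poly.plot_id] = (
                f"only {rough.defined.size} defined roughness values")
            continue
        traits.append(canopy_roughness(rough, genotype=poly.genotype,
                                       combine=combine))
    return traits, failures
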
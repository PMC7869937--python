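"""Radiometric vegetation/soil classification and row extraction.

A single green-band cut-off (115 on the 8-bit scale by default) separates the
green canopy from the soil background. Within a clipped plot, plant rows are
recovered by voxelizing the points on a regular 3-D grid (0.15 m step) and
labeling occupied voxels into connected components; small components are
discarded and the two border rows dropped to avoid edge effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.metrics import accuracy_score, cohen_kappa_score

from .cloud import ColoredPointCloud

__all__ = [
    "ClassifiedCloud", "RowCluster", "classify_vegetation",
    "audit_classification", "extract_rows", "drop_border_rows",
]

GREEN_CUTOFF_DEFAULT = 115


@dataclass
class ClassifiedCloud:
    """Exact vegetation/soil partition of an input cloud."""

    vegetation: ColoredPointCloud
    soil: ColoredPointCloud
    cutoff_used: int
    direction: str = "veg_ge_cutoff"
    vegetation_mask: np.ndarray | None = None

    @property
    def n_vegetation(self) -> int:
        return len(self.vegetation)

    @property
    def n_soil(self) -> int:
        return len(self.soil)


@dataclass
class RowCluster:
    """One plant row: the points of a voxel connected component."""

    row_id: int
    points: ColoredPointCloud
    voxel_count: int
    mean_cross_row: float = 0.0


def classify_vegetation(cloud: ColoredPointCloud,
                        green_cutoff: int = GREEN_CUTOFF_DEFAULT,
                        direction: str = "veg_ge_cutoff") -> ClassifiedCloud:
    """Threshold the green channel into vegetation and soil.

    Under ``veg_ge_cutoff`` (default) points with g >= cutoff are vegetation;
    ``veg_lt_cutoff`` inverts the rule for unusual soil radiometry. The two
    outputs partition the input exactly.
    """
    if not 0 <= green_cutoff <= 255:
        raise ValueError("green_cutoff must be an 8-bit value")
    if direction not in ("veg_ge_cutoff", "veg_lt_cutoff"):
        raise ValueError(f"unknown direction {direction!r}")
    g = cloud.rgb[:, 1].astype(int)
    veg_mask = g >= green_cutoff if direction == "veg_ge_cutoff" else g < green_cutoff
    return ClassifiedCloud(
        vegetation=cloud.select(veg_mask, provenance="vegetation"),
        soil=cloud.select(~veg_mask, provenance="soil"),
        cutoff_used=green_cutoff,
        direction=direction,
        vegetation_mask=veg_mask,
    )


def audit_classification(classified: ClassifiedCloud, truth_labels: np.ndarray,
                         n_sample: int = 1000, seed: int | None = 0
                         ) -> tuple[float, float]:
    """Spot-check a classification against ground truth labels.

    Mirrors a manual audit: ``n_sample`` points are drawn without replacement
    (all points if the cloud is smaller) and overall accuracy plus Cohen's
    kappa computed from the resulting 2x2 confusion table. ``truth_labels``
    is a boolean array (True = vegetation) aligned with the classified input.
    """
    truth = np.asarray(truth_labels, dtype=bool)
    pred = classified.vegetation_mask
    if pred is None:
        raise ValueError("classified cloud carries no per-point mask to audit")
    if len(truth) != len(pred):
        raise ValueError("truth labels do not align with the classified cloud")
    rng = np.random.default_rng(seed)
    n = min(n_sample, len(truth))
    idx = rng.choice(len(truth), size=n, replace=False)
    t, p = truth[idx], pred[idx]
    accuracy = float(accuracy_score(t, p))
    if np.all(t == t[0]) and np.all(p == p[0]) and t[0] == p[0]:
        kappa = 1.0  # single-cell table: perfect agreement
    else:
        kappa = float(cohen_kappa_score(t, p))
    return accuracy, kappa


def _voxel_labels(xyz: np.ndarray, grid_step: float, connectivity: int
                  ) -> tuple[np.ndarray, int]:
    """Label each point with its voxel connected component (0-based)."""
    origin = xyz.min(axis=0)
    ijk = np.floor((xyz - origin) / grid_step).astype(np.int64)
    # points exactly on the max face land one cell over; harmless, keep as is
    shape = ijk.max(axis=0) + 1
    if np.prod(shape) > 2e8:
        raise MemoryError(
            f"voxel grid {tuple(shape)} too large; increase grid_step")
    occ = np.zeros(shape, dtype=bool)
    occ[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
    structure = ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)
    labels, n_comp = ndimage.label(occ, structure=structure)
    return labels[ijk[:, 0], ijk[:, 1], ijk[:, 2]] - 1, n_comp


def _cross_row_axis(means: np.ndarray) -> int:
    """Pick the horizontal axis along which cluster centers spread most."""
    if len(means) < 2:
        return 0
    return int(np.argmax(means[:, :2].var(axis=0)))


def extract_rows(plot_cloud: ColoredPointCloud, grid_step: float = 0.15,
                 min_cluster_size: int = 50, connectivity: int = 26
                 ) -> list[RowCluster]:
    """Split a plot cloud into plant rows by voxel connected components.

    The space is divided into a regular 3-D grid of ``grid_step`` anchored at
    the plot's minimum corner; occupied voxels are linked into components
    (26-connectivity by default, 6 optional). Components with fewer than
    ``min_cluster_size`` points are discarded as not representing homogeneous
    plant growth. Rows come back ordered by their mean cross-row coordinate.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    if len(plot_cloud) == 0:
        raise ValueError("plot cloud is empty")
    comp, n_comp = _voxel_labels(plot_cloud.xyz, grid_step, connectivity)
    clusters = []
    for c in range(n_comp):
        mask = comp == c
        n_pts = int(mask.sum())
        if n_pts < min_cluster_size:
            continue
        pts = plot_cloud.select(mask, provenance="row")
        voxels = np.unique(
            np.floor((pts.xyz - plot_cloud.xyz.min(axis=0)) / grid_step
                     ).astype(np.int64), axis=0)
        clusters.append(RowCluster(row_id=-1, points=pts,
                                   voxel_count=len(voxels)))
    if not clusters:
        return []
    means = np.array([c.points.xyz.mean(axis=0) for c in clusters])
    axis = _cross_row_axis(means)
    order = np.argsort(means[:, axis], kind="stable")
    out = []
    for new_id, i in enumerate(order):
        c = clusters[i]
        c.row_id = new_id
        c.mean_cross_row = float(means[i, axis])
        out.append(c)
    return out


def drop_border_rows(rows: list[RowCluster]) -> list[RowCluster]:
    """Remove the two extreme rows (border effect) and return the interior.

    With the standard 8-row plot layout this leaves the 6 analyzed rows.
    Requires at least 3 rows so an interior exists.
    """
    if len(rows) < 3:
        raise ValueError(f"need >= 3 rows to drop borders, got {len(rows)}")
    return rows[1:-1]
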
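"""Outlier removal and height calibration for SfM point clouds.

Dense photogrammetric clouds contain sparse gross outliers (mismatched
features, sky points). Two sequential filters handle them:

1. :func:`statistical_outlier_removal` — remove points whose mean distance to
   their k nearest neighbors is more than ``n_sigma`` standard deviations
   above the cloud-wide mean of that statistic.
2. :func:`plane_fit_outlier_removal` — remove points whose orthogonal
   distance to the total-least-squares plane of their k-neighborhood is more
   than ``n_sigma`` standard deviations above the cloud-wide mean distance.

Both fit the Gaussian (mu, sigma) globally over the cloud and use a one-sided
threshold: only unusually *large* distances mark outliers. Absolute elevation
is then calibrated against surveyed reference bars with
:func:`adjust_height`.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import cKDTree

from .cloud import ColoredPointCloud

__all__ = [
    "HeightBar", "FilterReport", "statistical_outlier_removal",
    "plane_fit_outlier_removal", "adjust_height", "fit_plane_tls",
]

#: Neighborhoods whose covariance is this close to rank < 2 are treated as
#: collinear; the query point is retained and counted in the report.
_COLLINEAR_RTOL = 1e-12


@dataclass
class HeightBar:
    """A surveyed reference bar: GNSS elevation vs elevation read from the cloud."""

    bar_id: str
    measured_z: float
    cloud_z: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.measured_z) and np.isfinite(self.cloud_z)):
            raise ValueError(f"bar {self.bar_id!r}: elevations must be finite")


@dataclass
class FilterReport:
    """Bookkeeping for one filtering pass."""

    filter_name: str
    n_input: int
    n_removed: int
    k: int
    n_sigma: float
    mu: float
    sigma: float
    n_degenerate: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_removed <= self.n_input):
            raise ValueError("removed count outside [0, n_input]")

    def to_dict(self) -> dict:
        return asdict(self)


def _require_enough_points(cloud: ColoredPointCloud, k: int) -> None:
    if len(cloud) <= k:
        raise ValueError(
            f"cloud has {len(cloud)} points but the filter needs more than "
            f"k={k}; lower k for small clouds")


def fit_plane_tls(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane through ``points`` ((m, 3), m >= 3).

    Returns ``(centroid, unit_normal)`` where the normal is the eigenvector of
    the neighborhood covariance with the smallest eigenvalue. Raises
    ``np.linalg.LinAlgError``-free; collinearity must be checked by the caller
    via the returned eigenvalues of :func:`_plane_and_spectrum`.
    """
    centroid, normal, _ = _plane_and_spectrum(points)
    return centroid, normal


def _plane_and_spectrum(points: np.ndarray):
    centroid = points.mean(axis=0)
    centered = points - centroid
    cov = centered.T @ centered
    eigvals, eigvecs = np.linalg.eigh(cov)
    return centroid, eigvecs[:, 0], eigvals


def point_to_plane_distance(point: np.ndarray, centroid: np.ndarray,
                            normal: np.ndarray) -> float:
    return float(abs(np.dot(point - centroid, normal)))


def mean_knn_distance(cloud: ColoredPointCloud, k: int) -> np.ndarray:
    """Per-point mean Euclidean distance to the k nearest neighbors (self excluded)."""
    _require_enough_points(cloud, k)
    tree = cKDTree(cloud.xyz)
    dist, _ = tree.query(cloud.xyz, k=k + 1)  # first hit is the point itself
    return dist[:, 1:].mean(axis=1)


def statistical_outlier_removal(cloud: ColoredPointCloud, k: int = 20,
                                n_sigma: float = 3.0
                                ) -> tuple[ColoredPointCloud, FilterReport]:
    """Remove points whose mean k-NN distance exceeds mu + n_sigma * sigma.

    The per-point statistic is the mean distance from the point to its ``k``
    nearest neighbors; a Gaussian is fitted to the statistic over the whole
    cloud. With zero variance (perfectly regular spacing) nothing is removed.
    """
    d = mean_knn_distance(cloud, k)
    mu, sigma = float(d.mean()), float(d.std(ddof=1))
    keep = d <= mu + n_sigma * sigma
    report = FilterReport("statistical_outlier_removal", len(cloud),
                          int((~keep).sum()), k, n_sigma, mu, sigma)
    return cloud.select(keep, provenance="filtered"), report


def plane_distances(cloud: ColoredPointCloud, k: int = 20
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Orthogonal distance from each point to the TLS plane of its k neighbors.

    The query point is excluded from its own fit. Returns ``(distances,
    degenerate)`` where ``degenerate`` flags collinear neighborhoods whose
    distance is undefined (NaN).
    """
    _require_enough_points(cloud, k)
    tree = cKDTree(cloud.xyz)
    _, idx = tree.query(cloud.xyz, k=k + 1)
    neighbors = cloud.xyz[idx[:, 1:]]          # (n, k, 3)
    centroids = neighbors.mean(axis=1)
    centered = neighbors - centroids[:, None, :]
    cov = np.einsum("nki,nkj->nij", centered, centered)
    eigvals, eigvecs = np.linalg.eigh(cov)
    normals = eigvecs[:, :, 0]
    degenerate = eigvals[:, 1] <= _COLLINEAR_RTOL * np.maximum(eigvals[:, 2], 1.0)
    dist = np.abs(np.einsum("ni,ni->n", cloud.xyz - centroids, normals))
    dist[degenerate] = np.nan
    return dist, degenerate


def plane_fit_outlier_removal(cloud: ColoredPointCloud, k: int = 20,
                              n_sigma: float = 3.0
                              ) -> tuple[ColoredPointCloud, FilterReport]:
    """Remove points far from the local surface.

    For each point a total-least-squares plane is fitted to its ``k`` nearest
    neighbors and the point's orthogonal distance recorded; a Gaussian is
    fitted to these distances cloud-wide and points beyond mu + n_sigma *
    sigma are removed. Points with degenerate (collinear) neighborhoods are
    retained and counted in the report.
    """
    dist, degenerate = plane_distances(cloud, k)
    valid = dist[~degenerate]
    if valid.size < 2:  # nothing to fit a Gaussian to: keep everything
        mu = sigma = float("nan")
        keep = np.ones(len(cloud), dtype=bool)
    else:
        mu, sigma = float(valid.mean()), float(valid.std(ddof=1))
        keep = ~(dist > mu + n_sigma * sigma)  # NaN compares False -> kept
    report = FilterReport("plane_fit_outlier_removal", len(cloud),
                          int((~keep).sum()), k, n_sigma, mu, sigma,
                          n_degenerate=int(degenerate.sum()))
    return cloud.select(keep, provenance="filtered"), report


def adjust_height(cloud: ColoredPointCloud, bars: list[HeightBar]
                  ) -> tuple[ColoredPointCloud, float, np.ndarray]:
    """Shift the cloud so its elevations match the surveyed height bars.

    The offset is the mean over bars of (measured_z - cloud_z); the returned
    residuals are the per-bar mismatches after the shift.
    """
    if not bars:
        raise ValueError("at least one height bar is required")
    deltas = np.array([b.measured_z - b.cloud_z for b in bars])
    offset = float(deltas.mean())
    residuals = deltas - offset
    shifted = cloud.translated([0.0, 0.0, offset])
    return shifted, offset, residuals
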
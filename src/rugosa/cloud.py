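"""Colored point cloud container.

A :class:`ColoredPointCloud` is the carrier moved through every pipeline
stage: N points with metric 3-D coordinates and 8-bit RGB radiometry, plus a
free-text coordinate-system tag and a provenance stage name.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Pipeline stages a cloud may carry as provenance.
STAGES = ("raw", "filtered", "regularized", "vegetation", "soil", "plot", "row")


@dataclass
class ColoredPointCloud:
    """N points with coordinates in meters and 8-bit RGB color.

    Parameters
    ----------
    xyz : (N, 3) float64 array
        Point coordinates in meters (easting-like x, northing-like y,
        elevation z). Must be finite.
    rgb : (N, 3) uint8 array
        Color channels in [0, 255].
    crs_label : str
        Free-text coordinate-system tag (e.g. "EPSG:32616"); not interpreted.
    provenance : str
        Pipeline stage that produced this cloud; one of :data:`STAGES`.
    """

    xyz: np.ndarray
    rgb: np.ndarray
    crs_label: str = ""
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.xyz = np.ascontiguousarray(self.xyz, dtype=np.float64).reshape(-1, 3)
        rgb = np.asarray(self.rgb)
        if rgb.size and (not np.issubdtype(rgb.dtype, np.integer)) and not np.all(
            rgb == np.round(rgb)
        ):
            raise ValueError("color channels must be integral")
        if rgb.size and (rgb.min() < 0 or rgb.max() > 255):
            raise ValueError("color channels must lie in [0, 255]")
        self.rgb = np.ascontiguousarray(rgb, dtype=np.uint8).reshape(-1, 3)
        if len(self.rgb) != len(self.xyz):
            raise ValueError(
                f"xyz has {len(self.xyz)} points but rgb has {len(self.rgb)}"
            )
        if self.xyz.size and not np.all(np.isfinite(self.xyz)):
            raise ValueError("coordinates must be finite")
        if self.provenance not in STAGES:
            raise ValueError(
                f"unknown provenance {self.provenance!r}; expected one of {STAGES}"
            )

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def select(self, index: np.ndarray, provenance: str | None = None
               ) -> "ColoredPointCloud":
        """Subset by boolean mask or integer index, order preserved."""
        return ColoredPointCloud(
            self.xyz[index],
            self.rgb[index],
            crs_label=self.crs_label,
            provenance=provenance or self.provenance,
        )

    def with_provenance(self, provenance: str) -> "ColoredPointCloud":
        return replace(self, provenance=provenance)

    def translated(self, offset) -> "ColoredPointCloud":
        """Return a copy rigidly translated by ``offset`` (3-vector, meters)."""
        off = np.asarray(offset, dtype=np.float64).reshape(3)
        return ColoredPointCloud(
            self.xyz + off, self.rgb, crs_label=self.crs_label,
            provenance=self.provenance,
        )


def empty_cloud(crs_label: str = "", provenance: str = "raw") -> ColoredPointCloud:
    return ColoredPointCloud(
        np.empty((0, 3)), np.empty((0, 3), dtype=np.uint8),
        crs_label=crs_label, provenance=provenance,
    )


def concatenate(clouds, provenance: str | None = None) -> ColoredPointCloud:
    """Stack clouds in order; provenance defaults to the first cloud's."""
    clouds = list(clouds)
    if not clouds:
        return empty_cloud()
    return ColoredPointCloud(
        np.vstack([c.xyz for c in clouds]),
        np.vstack([c.rgb for c in clouds]),
        crs_label=clouds[0].crs_label,
        provenance=provenance or clouds[0].provenance,
    )
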
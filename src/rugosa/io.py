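"""Readers/writers for colored point clouds and plot maps.

Supported point formats:

* **PLY** — ascii or binary_little_endian, ``x y z`` as float/double plus
  ``red green blue`` (uchar). Coordinates are written as float64 so a
  write/read round-trip is bitwise exact.
* **LAS 1.2** — point format 2 (XYZ + RGB), coordinates stored as scaled
  integers at 1 mm resolution with the offset anchored at the cloud minimum.
  Colors are stored in the 16-bit LAS channels as ``c * 257`` so 8-bit values
  round-trip exactly. LAZ compression is not supported.
* **XYZ** — whitespace-separated ``x y z r g b`` text, ``#`` comments allowed.

Plot maps (polygon → plot assignments) are read from a plain CSV
(``plot_id, genotype, vertex_index, x, y``) or a GeoJSON FeatureCollection of
polygons carrying ``plot_id``/``genotype`` properties.
"""

from __future__ import annotations

import io as _stdio
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .cloud import ColoredPointCloud, empty_cloud

__all__ = [
    "PlotPolygon", "PlotMap", "read_point_cloud", "write_point_cloud",
    "clip_by_polygon", "read_plot_map", "read_height_bars",
]


class PointCloudFormatError(ValueError):
    """Raised for malformed point-cloud files."""


class NoRadiometryError(PointCloudFormatError):
    """Raised when a file carries no RGB color attributes."""


# --------------------------------------------------------------------------
# plot polygons
# --------------------------------------------------------------------------

@dataclass
class PlotPolygon:
    """A plot boundary: a simple closed 2-D ring in meters plus labels."""

    plot_id: str
    vertices: np.ndarray  # (k, 2) ring, not necessarily repeated-closed
    genotype: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 2)
        # accept an explicitly closed ring; store it open
        if len(v) > 1 and np.array_equal(v[0], v[-1]):
            v = v[:-1]
        if len(np.unique(v, axis=0)) < 3:
            raise ValueError(f"plot {self.plot_id!r}: ring needs >= 3 distinct vertices")
        self.vertices = v
        ring = shapely.LinearRing(v)
        if not ring.is_simple or not ring.is_valid:
            raise ValueError(f"plot {self.plot_id!r}: ring is self-intersecting")

    @property
    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.vertices)

    @property
    def area(self) -> float:
        return float(self.polygon.area)


@dataclass
class PlotMap:
    """Collection of plot polygons with unique plot ids."""

    polygons: list[PlotPolygon] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.plot_id for p in self.polygons]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate plot ids: {dupes}")

    def __iter__(self):
        return iter(self.polygons)

    def __len__(self) -> int:
        return len(self.polygons)

    def __getitem__(self, plot_id: str) -> PlotPolygon:
        for p in self.polygons:
            if p.plot_id == plot_id:
                return p
        raise KeyError(plot_id)


def clip_by_polygon(cloud: ColoredPointCloud, polygon: PlotPolygon
                    ) -> ColoredPointCloud:
    """Return the points whose (x, y) fall inside ``polygon``.

    Boundary points are included (closed-polygon convention, as in common
    clipping tools). z and color are untouched and point order is preserved.
    """
    poly = polygon.polygon
    if poly.area == 0:
        raise ValueError(f"plot {polygon.plot_id!r}: degenerate polygon (area 0)")
    if len(cloud) == 0:
        return cloud.with_provenance("plot")
    pts = shapely.points(cloud.x, cloud.y)
    shapely.prepare(poly)
    mask = shapely.covers(poly, pts)
    return cloud.select(mask, provenance="plot")


# --------------------------------------------------------------------------
# XYZ text
# --------------------------------------------------------------------------

def _read_xyz(path: Path) -> ColoredPointCloud:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            body = line.split("#", 1)[0].strip()
            if not body:
                continue
            fields = body.split()
            if len(fields) < 6:
                if len(fields) >= 3:
                    raise NoRadiometryError(
                        f"{path}:{lineno}: no radiometry (expected x y z r g b)")
                raise PointCloudFormatError(
                    f"{path}:{lineno}: expected 6 fields, got {len(fields)}")
            try:
                rows.append([float(v) for v in fields[:6]])
            except ValueError as exc:
                raise PointCloudFormatError(f"{path}:{lineno}: {exc}") from exc
    if not rows:
        return empty_cloud()
    arr = np.asarray(rows, dtype=np.float64)
    return ColoredPointCloud(arr[:, :3], arr[:, 3:6].astype(np.uint8))


def _write_xyz(cloud: ColoredPointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("# x y z r g b\n")
        for (x, y, z), (r, g, b) in zip(cloud.xyz, cloud.rgb):
            fh.write(f"{x:.17g} {y:.17g} {z:.17g} {r} {g} {b}\n")


# --------------------------------------------------------------------------
# PLY
# --------------------------------------------------------------------------

_PLY_DTYPES = {
    "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
}
_COLOR_ALIASES = {"red": "red", "green": "green", "blue": "blue",
                  "diffuse_red": "red", "diffuse_green": "green",
                  "diffuse_blue": "blue"}


def _read_ply(path: Path) -> ColoredPointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise PointCloudFormatError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise PointCloudFormatError(f"{path}: truncated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                if tokens[1] == "vertex":
                    if n_vertex is not None:
                        raise PointCloudFormatError(f"{path}: duplicate vertex element")
                    n_vertex = int(tokens[2])
                    in_vertex = True
                else:
                    in_vertex = False
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise PointCloudFormatError(f"{path}: list property on vertex")
                if tokens[1] not in _PLY_DTYPES:
                    raise PointCloudFormatError(f"{path}: unknown type {tokens[1]!r}")
                props.append((tokens[2], _PLY_DTYPES[tokens[1]]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise PointCloudFormatError(f"{path}: unsupported PLY format {fmt!r}")
        if n_vertex is None:
            raise PointCloudFormatError(f"{path}: no vertex element")
        names = [n for n, _ in props]
        for coord in ("x", "y", "z"):
            if coord not in names:
                raise PointCloudFormatError(f"{path}: vertex lacks {coord!r}")
        colors = {_COLOR_ALIASES[n]: n for n in names if n in _COLOR_ALIASES}
        if set(colors) != {"red", "green", "blue"}:
            raise NoRadiometryError(f"{path}: no radiometry (missing RGB properties)")
        if fmt == "binary_little_endian":
            dtype = np.dtype([(n, "<" + t) for n, t in props])
            buf = fh.read(dtype.itemsize * n_vertex)
            if len(buf) != dtype.itemsize * n_vertex:
                raise PointCloudFormatError(f"{path}: truncated vertex data")
            data = np.frombuffer(buf, dtype=dtype)
        else:
            dtype = np.dtype([(n, t) for n, t in props])
            lines = []
            while len(lines) < n_vertex:
                line = fh.readline()
                if not line:
                    raise PointCloudFormatError(
                        f"{path}: truncated ascii data at record {len(lines)}")
                if line.strip():
                    lines.append(line.decode("ascii"))
            try:
                data = np.genfromtxt(_stdio.StringIO("".join(lines)), dtype=dtype)
            except ValueError as exc:
                raise PointCloudFormatError(f"{path}: {exc}") from exc
            data = np.atleast_1d(data)
    if n_vertex == 0:
        return empty_cloud()
    xyz = np.column_stack([data["x"], data["y"], data["z"]]).astype(np.float64)
    rgb = np.column_stack([data[colors["red"]], data[colors["green"]],
                           data[colors["blue"]]])
    return ColoredPointCloud(xyz, np.clip(np.round(rgb), 0, 255).astype(np.uint8))


def _write_ply(cloud: ColoredPointCloud, path: Path, binary: bool = True) -> None:
    n = len(cloud)
    header = [
        "ply",
        "format binary_little_endian 1.0" if binary else "format ascii 1.0",
        f"element vertex {n}",
        "property double x", "property double y", "property double z",
        "property uchar red", "property uchar green", "property uchar blue",
        "end_header",
    ]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            rec = np.empty(n, dtype=np.dtype(
                [("x", "<f8"), ("y", "<f8"), ("z", "<f8"),
                 ("red", "u1"), ("green", "u1"), ("blue", "u1")]))
            for i, name in enumerate(("x", "y", "z")):
                rec[name] = cloud.xyz[:, i]
            for i, name in enumerate(("red", "green", "blue")):
                rec[name] = cloud.rgb[:, i]
            fh.write(rec.tobytes())
        else:
            for (x, y, z), (r, g, b) in zip(cloud.xyz, cloud.rgb):
                fh.write(f"{x:.17g} {y:.17g} {z:.17g} {r} {g} {b}\n".encode("ascii"))


def write_mesh_ply(vertices: np.ndarray, faces: np.ndarray, colors: np.ndarray,
                   path) -> Path:
    """Export a triangle mesh (with per-vertex uchar RGB) as ascii PLY."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(vertices)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write("property uchar red\nproperty uchar green\nproperty uchar blue\n")
        fh.write(f"element face {len(faces)}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for (x, y, z), (r, g, b) in zip(vertices, colors):
            fh.write(f"{x:.17g} {y:.17g} {z:.17g} {r} {g} {b}\n")
        for a, b_, c in faces:
            fh.write(f"3 {a} {b_} {c}\n")
    return path


# --------------------------------------------------------------------------
# LAS 1.2, point format 2
# --------------------------------------------------------------------------

_LAS_HEADER = struct.Struct("<4sHH16sBB32s32sHHHLLBHL5L12d")
_LAS_SCALE = 0.001  # 1 mm

_LAS_POINT2 = np.dtype([
    ("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"), ("intensity", "<u2"),
    ("flags", "u1"), ("classification", "u1"), ("scan_angle", "i1"),
    ("user_data", "u1"), ("point_source", "<u2"),
    ("red", "<u2"), ("green", "<u2"), ("blue", "<u2"),
])


def _read_las(path: Path) -> ColoredPointCloud:
    with open(path, "rb") as fh:
        raw = fh.read(227)
        if len(raw) < 227 or raw[:4] != b"LASF":
            raise PointCloudFormatError(f"{path}: not a LAS file")
        fields = _LAS_HEADER.unpack(raw)
        offset_to_points = fields[11]
        point_format = fields[13] & 0x3F
        record_len = fields[14]
        n_points = fields[15]
        scales = fields[21:24]
        offsets = fields[24:27]
        if point_format in (0, 1):
            raise NoRadiometryError(
                f"{path}: LAS point format {point_format} carries no RGB")
        if point_format not in (2, 3):
            raise PointCloudFormatError(
                f"{path}: unsupported LAS point format {point_format}")
        color_off = 20 if point_format == 2 else 28
        fh.seek(offset_to_points)
        buf = fh.read(record_len * n_points)
        if len(buf) != record_len * n_points:
            raise PointCloudFormatError(f"{path}: truncated point data")
    if n_points == 0:
        return empty_cloud()
    stride = np.frombuffer(buf, dtype=np.uint8).reshape(n_points, record_len)
    xyz_raw = stride[:, :12].copy().view("<i4").reshape(n_points, 3)
    rgb16 = stride[:, color_off:color_off + 6].copy().view("<u2").reshape(n_points, 3)
    xyz = xyz_raw.astype(np.float64) * np.asarray(scales) + np.asarray(offsets)
    return ColoredPointCloud(xyz, (rgb16 // 257).astype(np.uint8))


def _write_las(cloud: ColoredPointCloud, path: Path) -> None:
    n = len(cloud)
    if n:
        lo, hi = cloud.xyz.min(axis=0), cloud.xyz.max(axis=0)
    else:
        lo = hi = np.zeros(3)
    rec = np.zeros(n, dtype=_LAS_POINT2)
    scaled = np.round((cloud.xyz - lo) / _LAS_SCALE) if n else np.empty((0, 3))
    if n and np.abs(scaled).max() > np.iinfo(np.int32).max:
        raise PointCloudFormatError("cloud extent overflows LAS 1 mm grid")
    for i, name in enumerate(("X", "Y", "Z")):
        rec[name] = scaled[:, i].astype(np.int64) if n else 0
    rec["flags"] = 0x11  # single return
    for i, name in enumerate(("red", "green", "blue")):
        rec[name] = cloud.rgb[:, i].astype(np.uint16) * 257
    header = _LAS_HEADER.pack(
        b"LASF", 0, 0, b"\0" * 16, 1, 2,
        b"rugosa".ljust(32, b"\0"), b"rugosa".ljust(32, b"\0"),
        1, 2020, 227, 227, 0, 2, _LAS_POINT2.itemsize, n,
        n, 0, 0, 0, 0,
        _LAS_SCALE, _LAS_SCALE, _LAS_SCALE, lo[0], lo[1], lo[2],
        hi[0], lo[0], hi[1], lo[1], hi[2], lo[2],
    )
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(rec.tobytes())


# --------------------------------------------------------------------------
# dispatch
# --------------------------------------------------------------------------

_FORMATS = ("ply", "las", "xyz")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
        if fmt == "txt":
            fmt = "xyz"
    if fmt not in _FORMATS:
        raise ValueError(f"unknown point-cloud format {fmt!r}; expected {_FORMATS}")
    return fmt


def read_point_cloud(path, format: str | None = None) -> ColoredPointCloud:
    """Read a colored point cloud; format inferred from the suffix if omitted.

    Raises :class:`NoRadiometryError` when the file has no RGB attributes and
    :class:`PointCloudFormatError` (with the offending record) on malformed
    input.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if not path.exists():
        raise FileNotFoundError(path)
    return {"ply": _read_ply, "las": _read_las, "xyz": _read_xyz}[fmt](path)


def write_point_cloud(cloud: ColoredPointCloud, path, format: str | None = None,
                      *, ascii_ply: bool = False) -> Path:
    """Write ``cloud`` to ``path``; returns the path written."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "ply":
        _write_ply(cloud, path, binary=not ascii_ply)
    elif fmt == "las":
        _write_las(cloud, path)
    else:
        _write_xyz(cloud, path)
    return path


# --------------------------------------------------------------------------
# plot maps and height bars
# --------------------------------------------------------------------------

def read_plot_map(path) -> PlotMap:
    """Read a plot map from CSV (plot_id, genotype, vertex_index, x, y) or
    GeoJSON (FeatureCollection of Polygons with plot_id/genotype properties)."""
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        with open(path) as fh:
            doc = json.load(fh)
        polys = []
        for feat in doc.get("features", []):
            geom = feat.get("geometry", {})
            if geom.get("type") != "Polygon":
                raise ValueError(f"{path}: non-polygon feature in plot map")
            props = feat.get("properties", {}) or {}
            polys.append(PlotPolygon(
                plot_id=str(props.get("plot_id", len(polys))),
                vertices=np.asarray(geom["coordinates"][0], dtype=float),
                genotype=str(props.get("genotype", "")),
            ))
        return PlotMap(polys)
    df = pd.read_csv(path, dtype={"plot_id": str, "genotype": str})
    required = {"plot_id", "vertex_index", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: plot-map CSV needs columns {sorted(required)}")
    polys = []
    for plot_id, grp in df.groupby("plot_id", sort=False):
        grp = grp.sort_values("vertex_index")
        genotype = str(grp["genotype"].iloc[0]) if "genotype" in grp else ""
        polys.append(PlotPolygon(plot_id=str(plot_id),
                                 vertices=grp[["x", "y"]].to_numpy(),
                                 genotype=genotype))
    return PlotMap(polys)


def write_plot_map(plot_map: PlotMap, path) -> Path:
    rows = []
    for poly in plot_map:
        for i, (x, y) in enumerate(poly.vertices):
            rows.append({"plot_id": poly.plot_id, "genotype": poly.genotype,
                         "vertex_index": i, "x": x, "y": y})
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_height_bars(path) -> pd.DataFrame:
    """Read surveyed height bars: CSV with bar_id, measured_z, cloud_z."""
    df = pd.read_csv(path, dtype={"bar_id": str})
    required = {"bar_id", "measured_z", "cloud_z"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: height-bar CSV needs columns {sorted(required)}")
    return df
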
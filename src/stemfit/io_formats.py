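"""Point-cloud containers and file I/O.

The :class:`PointCloud` is the currency of the whole pipeline: an ``(N, 3)``
float64 array of coordinates in metres (gravity-aligned z, as produced by an
IMU-aided SLAM map) plus optional named per-point scalar attributes.

Supported on-disk formats:

* **XYZ** — whitespace-delimited text, one point per line.  Extra columns are
  mapped to attributes when a ``#fields x y z name ...`` comment header names
  them, and ignored otherwise.
* **PLY** — ascii and binary_little_endian, with x/y/z stored as float32 or
  float64; extra vertex properties become attributes.
* **PCD** — v0.7, ascii and binary.
* **LAS** — optional; requires ``laspy``, and degrades with a clear error when
  that package is not installed.

Cropping a map to a surveyed plot uses a 2D polygon applied to (x, y) only,
with boundary points kept (matching the visual-crop convention of interactive
tools such as CloudCompare).
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import shapely

__all__ = [
    "PointCloud",
    "Polygon2D",
    "PointCloudIOError",
    "PointCloudParseError",
    "FeatureUnavailableError",
    "read_point_cloud",
    "write_point_cloud",
    "crop_polygon",
    "read_polygon",
    "write_polygon",
    "read_ground_truth",
    "write_ground_truth",
]


class PointCloudIOError(IOError):
    """A file could not be read or written."""


class PointCloudParseError(ValueError):
    """A record in a point-cloud file is malformed; names the offending record."""


class FeatureUnavailableError(RuntimeError):
    """An optional feature (e.g. LAS support) is missing its dependency."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class PointCloud:
    """N points in 3D, metres, with optional per-point scalar attributes."""

    coords: np.ndarray
    attributes: dict[str, np.ndarray] = field(default_factory=dict)
    frame_note: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.size == 0:
            self.coords = self.coords.reshape(0, 3)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (N, 3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coords contain non-finite values")
        clean = {}
        for name, values in self.attributes.items():
            values = np.asarray(values)
            if values.shape != (len(self.coords),):
                raise ValueError(
                    f"attribute {name!r} has length {values.shape}, expected ({len(self.coords)},)"
                )
            clean[name] = values
        self.attributes = clean

    def __len__(self) -> int:
        return len(self.coords)

    def select(self, index: np.ndarray) -> "PointCloud":
        """Subset by boolean mask or integer indices; attributes carried through."""
        return PointCloud(
            self.coords[index],
            {k: v[index] for k, v in self.attributes.items()},
            self.frame_note,
        )

    @staticmethod
    def concat(clouds: list["PointCloud"], frame_note: str = "") -> "PointCloud":
        """Stack clouds; only attributes present in every part are kept."""
        if not clouds:
            return PointCloud(np.empty((0, 3)))
        coords = np.concatenate([c.coords for c in clouds], axis=0)
        common = set(clouds[0].attributes)
        for c in clouds[1:]:
            common &= set(c.attributes)
        attrs = {
            k: np.concatenate([c.attributes[k] for c in clouds]) for k in sorted(common)
        }
        return PointCloud(coords, attrs, frame_note)


@dataclass
class Polygon2D:
    """Simple (non-self-intersecting) polygon in the horizontal plane, metres."""

    vertices: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        if not np.all(np.isfinite(self.vertices)):
            raise ValueError("polygon vertices must be finite")
        geom = shapely.Polygon(self.vertices)
        if geom.area <= 0.0:
            raise ValueError("degenerate polygon: zero area")
        if not geom.is_valid:
            raise ValueError("polygon is not simple (self-intersecting)")
        self._geom = geom

    @property
    def shapely(self) -> shapely.Polygon:
        return self._geom


# ---------------------------------------------------------------------------
# XYZ text
# ---------------------------------------------------------------------------


def _read_xyz(path: Path) -> PointCloud:
    fields: list[str] | None = None
    rows: list[list[float]] = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#"):
                body = stripped.lstrip("#").strip()
                if body.startswith("fields"):
                    fields = body.split()[1:]
                continue
            parts = stripped.split()
            if len(parts) < 3:
                raise PointCloudParseError(
                    f"{path}: line {lineno}: expected >= 3 fields, got {len(parts)}"
                )
            try:
                rows.append([float(v) for v in parts])
            except ValueError as exc:
                raise PointCloudParseError(f"{path}: line {lineno}: {exc}") from exc
    if not rows:
        return PointCloud(np.empty((0, 3)))
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        bad = next(i for i, r in enumerate(rows, start=1) if len(r) != width)
        raise PointCloudParseError(f"{path}: inconsistent column count at record {bad}")
    data = np.asarray(rows, dtype=np.float64)
    attrs: dict[str, np.ndarray] = {}
    if fields is not None and len(fields) >= 3:
        for j, name in enumerate(fields[3:], start=3):
            if j < data.shape[1]:
                attrs[name] = data[:, j]
    return PointCloud(data[:, :3], attrs)


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    names = sorted(cloud.attributes)
    with open(path, "w") as fh:
        if names:
            fh.write("#fields x y z " + " ".join(names) + "\n")
        cols = [cloud.coords] + [
            np.asarray(cloud.attributes[n], dtype=np.float64)[:, None] for n in names
        ]
        data = np.hstack(cols) if len(cloud) else np.empty((0, 3 + len(names)))
        for row in data:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# PLY (ascii / binary_little_endian)
# ---------------------------------------------------------------------------

_PLY_DTYPES = {
    "float": "<f4",
    "float32": "<f4",
    "double": "<f8",
    "float64": "<f8",
    "uchar": "<u1",
    "uint8": "<u1",
    "char": "<i1",
    "int8": "<i1",
    "short": "<i2",
    "int16": "<i2",
    "ushort": "<u2",
    "uint16": "<u2",
    "int": "<i4",
    "int32": "<i4",
    "uint": "<u4",
    "uint32": "<u4",
}


def _read_ply(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        magic = fh.readline().strip()
        if magic != b"ply":
            raise PointCloudParseError(f"{path}: not a PLY file (bad magic)")
        fmt = None
        n_vertex = None
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise PointCloudParseError(f"{path}: unexpected EOF in header")
            tokens = line.decode("ascii", errors="replace").split()
            if not tokens or tokens[0] == "comment":
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise PointCloudParseError(f"{path}: list properties unsupported for vertices")
                props.append((tokens[2], tokens[1]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise PointCloudParseError(f"{path}: unsupported PLY format {fmt!r}")
        if n_vertex is None:
            raise PointCloudParseError(f"{path}: no vertex element in header")
        names = [p[0] for p in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise PointCloudParseError(f"{path}: vertex element lacks property {axis!r}")
        dtype = np.dtype([(name, _PLY_DTYPES[t]) for name, t in props])
        if fmt == "ascii":
            raw_rows = []
            for i in range(n_vertex):
                line = fh.readline()
                parts = line.split()
                if len(parts) != len(props):
                    raise PointCloudParseError(
                        f"{path}: vertex record {i}: expected {len(props)} fields, got {len(parts)}"
                    )
                raw_rows.append(tuple(float(v) for v in parts))
            table = np.array(raw_rows, dtype=dtype) if raw_rows else np.empty(0, dtype=dtype)
        else:
            buf = fh.read(dtype.itemsize * n_vertex)
            if len(buf) != dtype.itemsize * n_vertex:
                raise PointCloudParseError(f"{path}: truncated binary vertex data")
            table = np.frombuffer(buf, dtype=dtype)
    coords = np.column_stack(
        [table["x"].astype(np.float64), table["y"].astype(np.float64), table["z"].astype(np.float64)]
    )
    attrs = {
        name: np.asarray(table[name], dtype=np.float64)
        for name in names
        if name not in ("x", "y", "z")
    }
    return PointCloud(coords if len(table) else np.empty((0, 3)), attrs)


def _write_ply(cloud: PointCloud, path: Path, binary: bool, coord_dtype: str) -> None:
    ply_type = {"<f4": "float", "<f8": "double"}[np.dtype(coord_dtype).str]
    names = sorted(cloud.attributes)
    header = ["ply"]
    header.append(
        "format binary_little_endian 1.0" if binary else "format ascii 1.0"
    )
    header.append(f"element vertex {len(cloud)}")
    for axis in ("x", "y", "z"):
        header.append(f"property {ply_type} {axis}")
    for name in names:
        header.append(f"property double {name}")
    header.append("end_header")
    dtype = np.dtype(
        [(ax, coord_dtype) for ax in ("x", "y", "z")] + [(n, "<f8") for n in names]
    )
    table = np.empty(len(cloud), dtype=dtype)
    for j, ax in enumerate(("x", "y", "z")):
        table[ax] = cloud.coords[:, j]
    for n in names:
        table[n] = np.asarray(cloud.attributes[n], dtype=np.float64)
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(table.tobytes())
        else:
            out = io.StringIO()
            for row in table:
                out.write(" ".join(f"{float(v):.17g}" for v in row) + "\n")
            fh.write(out.getvalue().encode("ascii"))


# ---------------------------------------------------------------------------
# PCD v0.7 (ascii / binary)
# ---------------------------------------------------------------------------

_PCD_TYPE = {("F", 4): "<f4", ("F", 8): "<f8", ("I", 1): "<i1", ("I", 2): "<i2",
             ("I", 4): "<i4", ("U", 1): "<u1", ("U", 2): "<u2", ("U", 4): "<u4"}


def _read_pcd(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        header: dict[str, list[str]] = {}
        while True:
            line = fh.readline()
            if not line:
                raise PointCloudParseError(f"{path}: unexpected EOF in PCD header")
            text = line.decode("ascii", errors="replace").strip()
            if not text or text.startswith("#"):
                continue
            key, *vals = text.split()
            header[key.upper()] = vals
            if key.upper() == "DATA":
                break
        try:
            fields = header["FIELDS"]
            sizes = [int(v) for v in header["SIZE"]]
            types = header["TYPE"]
            counts = [int(v) for v in header.get("COUNT", ["1"] * len(fields))]
            n_points = int(header["POINTS"][0])
            data_mode = header["DATA"][0]
        except KeyError as exc:
            raise PointCloudParseError(f"{path}: PCD header missing {exc}") from exc
        if any(c != 1 for c in counts):
            raise PointCloudParseError(f"{path}: multi-count PCD fields unsupported")
        for axis in ("x", "y", "z"):
            if axis not in fields:
                raise PointCloudParseError(f"{path}: PCD lacks field {axis!r}")
        dtype = np.dtype(
            [(f, _PCD_TYPE[(t, s)]) for f, t, s in zip(fields, types, sizes)]
        )
        if data_mode == "ascii":
            rows = []
            for i in range(n_points):
                parts = fh.readline().split()
                if len(parts) != len(fields):
                    raise PointCloudParseError(
                        f"{path}: point record {i}: expected {len(fields)} fields, got {len(parts)}"
                    )
                rows.append(tuple(float(v) for v in parts))
            table = np.array(rows, dtype=dtype) if rows else np.empty(0, dtype=dtype)
        elif data_mode == "binary":
            buf = fh.read(dtype.itemsize * n_points)
            if len(buf) != dtype.itemsize * n_points:
                raise PointCloudParseError(f"{path}: truncated binary PCD data")
            table = np.frombuffer(buf, dtype=dtype)
        else:
            raise PointCloudParseError(f"{path}: unsupported PCD data mode {data_mode!r}")
    coords = np.column_stack(
        [table[ax].astype(np.float64) for ax in ("x", "y", "z")]
    )
    attrs = {
        f: np.asarray(table[f], dtype=np.float64) for f in fields if f not in ("x", "y", "z")
    }
    return PointCloud(coords if len(table) else np.empty((0, 3)), attrs)


def _write_pcd(cloud: PointCloud, path: Path, binary: bool, coord_dtype: str) -> None:
    names = sorted(cloud.attributes)
    size = np.dtype(coord_dtype).itemsize
    fields = ["x", "y", "z"] + names
    sizes = [size] * 3 + [8] * len(names)
    types = ["F"] * len(fields)
    header = [
        "# .PCD v0.7 - Point Cloud Data file format",
        "VERSION 0.7",
        "FIELDS " + " ".join(fields),
        "SIZE " + " ".join(str(s) for s in sizes),
        "TYPE " + " ".join(types),
        "COUNT " + " ".join("1" for _ in fields),
        f"WIDTH {len(cloud)}",
        "HEIGHT 1",
        "VIEWPOINT 0 0 0 1 0 0 0",
        f"POINTS {len(cloud)}",
        "DATA " + ("binary" if binary else "ascii"),
    ]
    dtype = np.dtype(
        [(ax, coord_dtype) for ax in ("x", "y", "z")] + [(n, "<f8") for n in names]
    )
    table = np.empty(len(cloud), dtype=dtype)
    for j, ax in enumerate(("x", "y", "z")):
        table[ax] = cloud.coords[:, j]
    for n in names:
        table[n] = np.asarray(cloud.attributes[n], dtype=np.float64)
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        if binary:
            fh.write(table.tobytes())
        else:
            out = io.StringIO()
            for row in table:
                out.write(" ".join(f"{float(v):.17g}" for v in row) + "\n")
            fh.write(out.getvalue().encode("ascii"))


# ---------------------------------------------------------------------------
# LAS (optional)
# ---------------------------------------------------------------------------


def _read_las(path: Path) -> PointCloud:
    try:
        import laspy  # type: ignore
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise FeatureUnavailableError(
            "LAS/LAZ support requires the optional 'laspy' package "
            "(install stemfit[las])"
        ) from exc
    las = laspy.read(str(path))  # pragma: no cover
    coords = np.column_stack([las.x, las.y, las.z])  # pragma: no cover
    attrs = {}  # pragma: no cover
    if hasattr(las, "intensity"):  # pragma: no cover
        attrs["intensity"] = np.asarray(las.intensity, dtype=np.float64)
    return PointCloud(coords, attrs)  # pragma: no cover


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

_EXT_FORMAT = {".ply": "ply", ".pcd": "pcd", ".xyz": "xyz", ".txt": "xyz",
               ".las": "las", ".laz": "las"}


def _resolve_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    ext = path.suffix.lower()
    if ext not in _EXT_FORMAT:
        raise PointCloudIOError(f"cannot infer point-cloud format from extension {ext!r}")
    return _EXT_FORMAT[ext]


def read_point_cloud(path, format: str = "auto") -> PointCloud:
    """Read a point cloud from PLY, PCD, XYZ text or (optionally) LAS.

    Parameters
    ----------
    path : path-like
    format : {"auto", "ply", "pcd", "xyz", "las"}
        ``auto`` infers from the file extension.
    """
    path = Path(path)
    if not path.is_file():
        raise PointCloudIOError(f"no such file: {path}")
    fmt = _resolve_format(path, format)
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "pcd":
        return _read_pcd(path)
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "las":
        return _read_las(path)
    raise PointCloudIOError(f"unknown format {fmt!r}")


def write_point_cloud(cloud: PointCloud, path, format: str = "auto",
                      binary: bool = True, coord_dtype: str = "float64") -> None:
    """Write a point cloud; ``binary`` and ``coord_dtype`` apply to PLY/PCD.

    Text formats are written at full float64 precision so that a write→read
    round-trip is lossless; binary output with ``coord_dtype='float32'``
    round-trips to float32 representability.
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise PointCloudIOError(f"parent directory does not exist: {path.parent}")
    fmt = _resolve_format(path, format)
    dtype = {"float32": "<f4", "float64": "<f8"}.get(coord_dtype)
    if dtype is None:
        raise ValueError(f"coord_dtype must be float32 or float64, got {coord_dtype!r}")
    if fmt == "ply":
        _write_ply(cloud, path, binary=binary, coord_dtype=dtype)
    elif fmt == "pcd":
        _write_pcd(cloud, path, binary=binary, coord_dtype=dtype)
    elif fmt == "xyz":
        _write_xyz(cloud, path)
    elif fmt == "las":
        raise FeatureUnavailableError("writing LAS is not supported")
    else:
        raise PointCloudIOError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# polygon crop + tabular ground truth
# ---------------------------------------------------------------------------


def crop_polygon(cloud: PointCloud, polygon: Polygon2D) -> PointCloud:
    """Keep points whose (x, y) lies inside or on the boundary of ``polygon``.

    z is ignored by the test; attributes are carried through; the input cloud
    is left unmodified.
    """
    if len(cloud) == 0:
        return cloud.select(np.zeros(0, dtype=bool))
    keep = shapely.intersects_xy(polygon.shapely, cloud.coords[:, 0], cloud.coords[:, 1])
    return cloud.select(np.asarray(keep, dtype=bool))


def read_polygon(path) -> Polygon2D:
    """Load a crop polygon from a CSV of ``x,y`` rows (optional header)."""
    df = pd.read_csv(path, header=None, comment="#")
    if df.iloc[0].astype(str).str.contains("[A-Za-z]").any():
        df = df.iloc[1:]
    verts = df.iloc[:, :2].astype(float).to_numpy()
    return Polygon2D(verts)


def write_polygon(polygon: Polygon2D, path) -> None:
    pd.DataFrame(polygon.vertices, columns=["x", "y"]).to_csv(path, index=False)


GROUND_TRUTH_COLUMNS = ["tree_id", "x", "y", "dbh_cm"]


def _validate_ground_truth(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in GROUND_TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ground-truth table missing columns {missing}")
    df = df[GROUND_TRUTH_COLUMNS].copy()
    if df["tree_id"].duplicated().any():
        raise ValueError("ground-truth tree_id values must be unique")
    if (df["dbh_cm"] <= 0).any():
        raise ValueError("ground-truth dbh_cm values must be positive")
    return df


def read_ground_truth(path) -> pd.DataFrame:
    """Read a stem table CSV with header ``tree_id,x,y,dbh_cm`` (x, y in m)."""
    return _validate_ground_truth(pd.read_csv(path))


def write_ground_truth(table: pd.DataFrame, path) -> None:
    _validate_ground_truth(table).to_csv(path, index=False)
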
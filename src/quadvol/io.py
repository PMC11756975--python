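"""Point-cloud containers and file I/O.

Supports the three formats the field workflow produces: PLY (ascii or
binary little-endian), LAS 1.2 (point formats 0-3, uncompressed), and
whitespace-delimited ASCII ``x y z [r g b]``.  The readers and writers
here are deliberately minimal — coordinates in metres, optional RGB,
optional per-point class label — and are lossless for that subset.

Label convention: 0 = unlabeled, 1 = ground, 2 = vegetation (nonground,
i.e. live vegetation plus litter).  In LAS files ground is stored as
ASPRS class 2 and vegetation as class 4 (medium vegetation); on read,
ASPRS classes 3/4/5 all collapse to the vegetation label.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import QuadratFrame

LABEL_UNLABELED = 0
LABEL_GROUND = 1
LABEL_VEGETATION = 2

_LAS_GROUND = 2
_LAS_VEGETATION = 4  # ASPRS medium vegetation
_LAS_VEG_CODES = (3, 4, 5)


class PointCloudFormatError(ValueError):
    """Raised when a point-cloud file cannot be parsed."""


@dataclass
class PointCloud:
    """N x 3 coordinates in metres (z-up) with optional RGB and labels."""

    coords: np.ndarray
    rgb: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("point coordinates must be finite")
        n = len(self.coords)
        if self.rgb is not None:
            self.rgb = np.asarray(self.rgb).reshape(-1, 3)
            if len(self.rgb) != n:
                raise ValueError("rgb length does not match coords")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64).reshape(-1)
            if len(self.labels) != n:
                raise ValueError("labels length does not match coords")
            bad = ~np.isin(self.labels, (LABEL_UNLABELED, LABEL_GROUND, LABEL_VEGETATION))
            if bad.any():
                raise ValueError("labels must be in {0, 1, 2}")

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def x(self) -> np.ndarray:
        return self.coords[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.coords[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.coords[:, 2]

    def select(self, index: np.ndarray) -> "PointCloud":
        """Subset by boolean mask or integer index array; order preserved."""
        return PointCloud(
            coords=self.coords[index],
            rgb=None if self.rgb is None else self.rgb[index],
            labels=None if self.labels is None else self.labels[index],
        )

    def with_labels(self, labels: np.ndarray) -> "PointCloud":
        return PointCloud(coords=self.coords, rgb=self.rgb, labels=labels)


def clip_to_frame(cloud: PointCloud, frame: QuadratFrame) -> PointCloud:
    """Keep exactly the points whose (x, y) fall in the half-open frame rectangle.

    z is unrestricted and point order is preserved.  Idempotent.
    """
    if len(cloud) == 0:
        return cloud
    return cloud.select(frame.contains(cloud.coords))


# ---------------------------------------------------------------------------
# biomass tables
# ---------------------------------------------------------------------------

_BIOMASS_COLUMNS = ("plot_id", "annual_g", "perennial_g", "forb_g", "litter_g")


@dataclass(frozen=True)
class BiomassRecord:
    """Per-plot oven-dry weights (g) split by functional group."""

    plot_id: str
    annual_g: float
    perennial_g: float
    forb_g: float
    litter_g: float

    def __post_init__(self) -> None:
        for name in ("annual_g", "perennial_g", "forb_g", "litter_g"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be a finite non-negative weight, got {v}")

    @property
    def vegetation_total(self) -> float:
        """Live + standing-dead vegetation: annual + perennial + forb (g)."""
        return self.annual_g + self.perennial_g + self.forb_g

    @property
    def total(self) -> float:
        """Total above-ground biomass including litter (g)."""
        return self.vegetation_total + self.litter_g


def read_biomass_table(path: str | Path) -> list[BiomassRecord]:
    """Read the per-plot biomass CSV (plot_id,annual_g,perennial_g,forb_g,litter_g).

    Missing weights, negative weights and duplicate plot ids are errors —
    a silent zero would corrupt every downstream regression.
    """
    df = pd.read_csv(path, dtype={"plot_id": str})
    missing_cols = set(_BIOMASS_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"biomass table missing columns: {sorted(missing_cols)}")
    if df["plot_id"].duplicated().any():
        dups = df.loc[df["plot_id"].duplicated(), "plot_id"].tolist()
        raise ValueError(f"duplicate plot ids in biomass table: {dups}")
    weight_cols = list(_BIOMASS_COLUMNS[1:])
    if df[weight_cols].isna().any().any():
        bad = df.loc[df[weight_cols].isna().any(axis=1), "plot_id"].tolist()
        raise ValueError(f"missing component weights for plots: {bad}")
    return [
        BiomassRecord(
            plot_id=row.plot_id,
            annual_g=float(row.annual_g),
            perennial_g=float(row.perennial_g),
            forb_g=float(row.forb_g),
            litter_g=float(row.litter_g),
        )
        for row in df.itertuples(index=False)
    ]


def write_biomass_table(records: list[BiomassRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "plot_id": r.plot_id,
                "annual_g": r.annual_g,
                "perennial_g": r.perennial_g,
                "forb_g": r.forb_g,
                "litter_g": r.litter_g,
            }
            for r in records
        ]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# point cloud file formats
# ---------------------------------------------------------------------------


def read_point_cloud(path: str | Path, format_hint: str | None = None) -> PointCloud:
    """Read a PLY / LAS / ASCII-XYZ point cloud; format inferred from suffix.

    An empty file yields an empty cloud (N = 0), not an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        return _read_ply(path)
    if fmt == "las":
        return _read_las(path)
    if fmt == "laz":
        raise PointCloudFormatError("compressed LAZ is not supported; decompress to LAS")
    if fmt in ("xyz", "txt", "csv", ""):
        return _read_xyz(path)
    raise PointCloudFormatError(f"unknown point cloud format {fmt!r}")


def write_labeled_ply(
    cloud: PointCloud, path: str | Path, extra_scalars: dict[str, np.ndarray] | None = None
) -> None:
    """PLY writer that can attach extra small integer scalars (e.g. truth classes)."""
    _write_ply(cloud, Path(path), extra_scalars)


def write_point_cloud(cloud: PointCloud, path: str | Path, format_hint: str | None = None) -> None:
    path = Path(path)
    fmt = (format_hint or path.suffix.lstrip(".")).lower()
    if fmt == "ply":
        _write_ply(cloud, path)
    elif fmt == "las":
        _write_las(cloud, path)
    elif fmt in ("xyz", "txt"):
        _write_xyz(cloud, path)
    else:
        raise PointCloudFormatError(f"unknown point cloud format {fmt!r}")


# -- ASCII XYZ[RGB] ----------------------------------------------------------


def _read_xyz(path: Path) -> PointCloud:
    try:
        data = np.loadtxt(path, ndmin=2)
    except ValueError as exc:
        raise PointCloudFormatError(f"cannot parse {path} as XYZ text: {exc}") from exc
    if data.size == 0:
        return PointCloud(coords=np.empty((0, 3)))
    if data.shape[1] < 3:
        raise PointCloudFormatError(f"{path}: expected at least 3 columns, got {data.shape[1]}")
    rgb = data[:, 3:6] if data.shape[1] >= 6 else None
    return PointCloud(coords=data[:, :3], rgb=rgb)


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    if cloud.rgb is not None:
        data = np.column_stack([cloud.coords, cloud.rgb])
    else:
        data = cloud.coords
    np.savetxt(path, data, fmt="%.9g")


# -- PLY ---------------------------------------------------------------------

_PLY_DTYPES = {
    "char": "i1", "int8": "i1",
    "uchar": "u1", "uint8": "u1",
    "short": "i2", "int16": "i2",
    "ushort": "u2", "uint16": "u2",
    "int": "i4", "int32": "i4",
    "uint": "u4", "uint32": "u4",
    "float": "f4", "float32": "f4",
    "double": "f8", "float64": "f8",
}


def _read_ply(path: Path) -> PointCloud:
    columns = read_ply_columns(path)
    coords = np.column_stack([columns["x"], columns["y"], columns["z"]])
    rgb = None
    if all(c in columns for c in ("red", "green", "blue")):
        rgb = np.column_stack([columns["red"], columns["green"], columns["blue"]])
    labels = None
    for key in ("label", "classification", "scalar_label"):
        if key in columns:
            labels = columns[key].astype(np.int64)
            break
    return PointCloud(coords=coords, rgb=rgb, labels=labels)


def read_ply_columns(path: str | Path) -> dict[str, np.ndarray]:
    """All vertex properties of a PLY file as named float arrays."""
    path = Path(path)
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            raise PointCloudFormatError(f"{path}: not a PLY file")
        fmt = None
        n_vertex = 0
        props: list[tuple[str, str]] = []
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise PointCloudFormatError(f"{path}: truncated PLY header")
            tokens = line.decode("ascii", "replace").split()
            if not tokens:
                continue
            if tokens[0] == "format":
                fmt = tokens[1]
            elif tokens[0] == "element":
                in_vertex = tokens[1] == "vertex"
                if in_vertex:
                    n_vertex = int(tokens[2])
            elif tokens[0] == "property" and in_vertex:
                if tokens[1] == "list":
                    raise PointCloudFormatError(f"{path}: list vertex properties unsupported")
                props.append((tokens[2], tokens[1]))
            elif tokens[0] == "end_header":
                break
        if fmt not in ("ascii", "binary_little_endian"):
            raise PointCloudFormatError(f"{path}: unsupported PLY format {fmt!r}")
        names = [p[0] for p in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise PointCloudFormatError(f"{path}: vertex element lacks {axis!r}")
        if fmt == "ascii":
            text = fh.read().decode("ascii")
            flat = np.array(text.split(), dtype=float)
            if flat.size != n_vertex * len(props):
                raise PointCloudFormatError(f"{path}: PLY vertex data size mismatch")
            table = flat.reshape(n_vertex, len(props))
            columns = {name: table[:, i] for i, (name, _t) in enumerate(props)}
        else:
            dtype = np.dtype([(name, "<" + _PLY_DTYPES[typ]) for name, typ in props])
            raw = fh.read(dtype.itemsize * n_vertex)
            if len(raw) < dtype.itemsize * n_vertex:
                raise PointCloudFormatError(f"{path}: truncated PLY vertex data")
            rec = np.frombuffer(raw, dtype=dtype, count=n_vertex)
            columns = {name: rec[name].astype(float) for name, _t in props}
    return columns


def _write_ply(cloud: PointCloud, path: Path, extra_scalars: dict[str, np.ndarray] | None = None) -> None:
    """Binary little-endian PLY with double-precision coordinates (lossless)."""
    props = [("x", "double"), ("y", "double"), ("z", "double")]
    arrays: list[np.ndarray] = [cloud.coords[:, 0], cloud.coords[:, 1], cloud.coords[:, 2]]
    if cloud.rgb is not None:
        props += [("red", "uchar"), ("green", "uchar"), ("blue", "uchar")]
        arrays += [cloud.rgb[:, i] for i in range(3)]
    if cloud.labels is not None:
        props += [("label", "uchar")]
        arrays += [cloud.labels]
    for name, values in (extra_scalars or {}).items():
        props += [(name, "uchar")]
        arrays += [np.asarray(values)]
    dtype = np.dtype([(name, "<" + _PLY_DTYPES[typ]) for name, typ in props])
    rec = np.empty(len(cloud), dtype=dtype)
    for (name, _typ), arr in zip(props, arrays):
        rec[name] = arr
    header = ["ply", "format binary_little_endian 1.0", f"element vertex {len(cloud)}"]
    header += [f"property {typ} {name}" for name, typ in props]
    header += ["end_header"]
    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        fh.write(rec.tobytes())


# -- LAS 1.2 -----------------------------------------------------------------

_LAS_HEADER_SIZE = 227
_LAS_POINT_BASE = {0: 20, 1: 28, 2: 26, 3: 34}
_LAS_SCALE = 1e-6  # 1 micrometre quantisation: lossless at the mm point spacings used here


def _read_las(path: Path) -> PointCloud:
    with open(path, "rb") as fh:
        header = fh.read(_LAS_HEADER_SIZE)
        if len(header) < _LAS_HEADER_SIZE or header[:4] != b"LASF":
            raise PointCloudFormatError(f"{path}: not a LAS file")
        offset_to_points = struct.unpack_from("<I", header, 96)[0]
        point_format = struct.unpack_from("<B", header, 104)[0]
        record_length = struct.unpack_from("<H", header, 105)[0]
        n_points = struct.unpack_from("<I", header, 107)[0]
        scale = struct.unpack_from("<3d", header, 131)
        offset = struct.unpack_from("<3d", header, 155)
        if point_format not in _LAS_POINT_BASE:
            raise PointCloudFormatError(f"{path}: unsupported LAS point format {point_format}")
        if record_length < _LAS_POINT_BASE[point_format]:
            raise PointCloudFormatError(f"{path}: record length too small")
        fh.seek(offset_to_points)
        raw = fh.read(record_length * n_points)
        if len(raw) < record_length * n_points:
            raise PointCloudFormatError(f"{path}: truncated LAS point data")
    dtype = np.dtype(
        {
            "names": ["X", "Y", "Z", "classification"],
            "formats": ["<i4", "<i4", "<i4", "u1"],
            "offsets": [0, 4, 8, 15],
            "itemsize": record_length,
        }
    )
    rec = np.frombuffer(raw, dtype=dtype, count=n_points)
    coords = np.column_stack(
        [
            rec["X"] * scale[0] + offset[0],
            rec["Y"] * scale[1] + offset[1],
            rec["Z"] * scale[2] + offset[2],
        ]
    )
    las_class = rec["classification"] & 0x1F  # low 5 bits; high bits are flags
    labels = np.full(n_points, LABEL_UNLABELED, dtype=np.int64)
    labels[las_class == _LAS_GROUND] = LABEL_GROUND
    labels[np.isin(las_class, _LAS_VEG_CODES)] = LABEL_VEGETATION
    return PointCloud(coords=coords, labels=labels)


def _write_las(cloud: PointCloud, path: Path) -> None:
    n = len(cloud)
    offsets = cloud.coords.min(axis=0) if n else np.zeros(3)
    scaled = np.round((cloud.coords - offsets) / _LAS_SCALE).astype(np.int64)
    if scaled.size and (np.abs(scaled) > np.iinfo(np.int32).max).any():
        raise PointCloudFormatError("coordinate extent too large for LAS micrometre scaling")
    record_length = _LAS_POINT_BASE[0]
    dtype = np.dtype(
        {
            "names": ["X", "Y", "Z", "intensity", "flags", "classification",
                      "scan_angle", "user_data", "point_source"],
            "formats": ["<i4", "<i4", "<i4", "<u2", "u1", "u1", "i1", "u1", "<u2"],
            "offsets": [0, 4, 8, 12, 14, 15, 16, 17, 18],
            "itemsize": record_length,
        }
    )
    rec = np.zeros(n, dtype=dtype)
    rec["X"], rec["Y"], rec["Z"] = scaled[:, 0], scaled[:, 1], scaled[:, 2]
    rec["flags"] = 0b00010001  # single return, first of one
    if cloud.labels is not None:
        las_class = np.zeros(n, dtype=np.uint8)
        las_class[cloud.labels == LABEL_GROUND] = _LAS_GROUND
        las_class[cloud.labels == LABEL_VEGETATION] = _LAS_VEGETATION
        rec["classification"] = las_class

    header = bytearray(_LAS_HEADER_SIZE)
    header[0:4] = b"LASF"
    struct.pack_into("<BB", header, 24, 1, 2)  # version 1.2
    struct.pack_into("<32s", header, 26, b"quadvol")
    struct.pack_into("<H", header, 94, _LAS_HEADER_SIZE)
    struct.pack_into("<I", header, 96, _LAS_HEADER_SIZE)  # offset to point data
    struct.pack_into("<I", header, 100, 0)  # no VLRs
    struct.pack_into("<B", header, 104, 0)  # point format 0
    struct.pack_into("<H", header, 105, record_length)
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<I", header, 111, n)  # returns by pulse (first)
    struct.pack_into("<3d", header, 131, _LAS_SCALE, _LAS_SCALE, _LAS_SCALE)
    struct.pack_into("<3d", header, 155, *offsets)
    lo = cloud.coords.min(axis=0) if n else np.zeros(3)
    hi = cloud.coords.max(axis=0) if n else np.zeros(3)
    struct.pack_into("<6d", header, 179, hi[0], lo[0], hi[1], lo[1], hi[2], lo[2])
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(rec.tobytes())
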
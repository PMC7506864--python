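"""File formats: point clouds (CSV, PLY, LAS 1.2) and DSM rasters (ASC, GeoTIFF).

Coordinates are metres in a local plot frame throughout.  The PLY writer
emits binary little-endian with double-precision x/y/z; the LAS writer emits
version 1.2, point data format 0, with a 0.1 mm coordinate scale.  DSMs are
written as ESRI ASCII grids (NODATA_value -9999) or single-band GeoTIFFs
(nodata encoded as NaN) with plain pixel-scale/tiepoint geotags.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import DSM, GridSpec, PointCloud

__all__ = [
    "read_point_cloud",
    "write_point_cloud",
    "write_asc",
    "read_asc",
    "write_geotiff",
    "read_geotiff",
]

_ASC_NODATA = -9999.0


# ---------------------------------------------------------------------------
# point clouds
# ---------------------------------------------------------------------------

def write_point_cloud(cloud: PointCloud, path, format: str | None = None) -> None:
    """Write a cloud as headered CSV, binary PLY, or LAS 1.2 (by extension)."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        pd.DataFrame(cloud.xyz, columns=["x", "y", "z"]).to_csv(path, index=False)
    elif fmt == "ply":
        _write_ply(cloud.xyz, path)
    elif fmt == "las":
        _write_las(cloud.xyz, path)
    else:
        raise ValueError(f"unsupported point cloud format {fmt!r}")


def read_point_cloud(path, format: str | None = None) -> PointCloud:
    """Read a point cloud; coordinates returned in metres.

    CSV needs an x,y,z header; a malformed record raises an error naming the
    first offending line.  An empty file yields an empty cloud with a
    warning.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        xyz = _read_csv(path)
    elif fmt == "ply":
        xyz = _read_ply(path)
    elif fmt == "las":
        xyz = _read_las(path)
    else:
        raise ValueError(f"unsupported point cloud format {fmt!r}")
    if xyz.shape[0] == 0:
        import warnings

        warnings.warn(f"{path} contains no points", stacklevel=2)
    return PointCloud(xyz)


def _read_csv(path: Path) -> np.ndarray:
    df = pd.read_csv(path, dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:3] != ["x", "y", "z"]:
        raise ValueError(f"{path}: expected header columns x,y,z, got {list(df.columns)}")
    if df.empty:
        return np.empty((0, 3))
    out = np.empty((len(df), 3))
    for k, col in enumerate(df.columns[:3]):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            # +2: one for the header line, one for 1-based numbering
            line = int(bad.idxmax()) + 2
            raise ValueError(
                f"{path}: non-numeric {col.strip().lower()} value "
                f"{df[col].iloc[line - 2]!r} on line {line}"
            )
        out[:, k] = vals.to_numpy()
    return out


_PLY_TYPES = {"float": ("<f4", 4), "float32": ("<f4", 4),
              "double": ("<f8", 8), "float64": ("<f8", 8)}


def _write_ply(xyz: np.ndarray, path: Path) -> None:
    header = (
        "ply\n"
        "format binary_little_endian 1.0\n"
        f"element vertex {xyz.shape[0]}\n"
        "property double x\n"
        "property double y\n"
        "property double z\n"
        "end_header\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(xyz, dtype="<f8").tobytes())


def _read_ply(path: Path) -> np.ndarray:
    with open(path, "rb") as fh:
        if fh.readline().strip() != b"ply":
            raise ValueError(f"{path}: not a PLY file")
        n_vertex = None
        props: list[tuple[str, str]] = []  # (dtype, name)
        in_vertex = False
        while True:
            line = fh.readline()
            if not line:
                raise ValueError(f"{path}: unterminated PLY header")
            parts = line.decode("ascii", "replace").split()
            if not parts:
                continue
            if parts[0] == "format":
                if parts[1] != "binary_little_endian":
                    raise ValueError(f"{path}: only binary_little_endian PLY supported")
            elif parts[0] == "element":
                in_vertex = parts[1] == "vertex"
                if in_vertex:
                    n_vertex = int(parts[2])
            elif parts[0] == "property" and in_vertex:
                if parts[1] not in _PLY_TYPES:
                    raise ValueError(f"{path}: unsupported vertex property type {parts[1]!r}")
                props.append((_PLY_TYPES[parts[1]][0], parts[2]))
            elif parts[0] == "end_header":
                break
        if n_vertex is None:
            raise ValueError(f"{path}: no vertex element")
        names = [name for _, name in props]
        for axis in ("x", "y", "z"):
            if axis not in names:
                raise ValueError(f"{path}: vertex element lacks property {axis!r}")
        dtype = np.dtype([(name, t) for t, name in props])
        data = np.frombuffer(fh.read(n_vertex * dtype.itemsize), dtype=dtype,
                             count=n_vertex)
        return np.column_stack([data[a].astype(float) for a in ("x", "y", "z")])


_LAS_HEADER = struct.Struct(
    "<4sHH16sBB32s32sHHHIIBHI" + "I" * 5 + "d" * 12
)
_LAS_POINT0 = struct.Struct("<lllHBBbBH")
_LAS_SCALE = 1e-4  # 0.1 mm coordinate resolution


def _write_las(xyz: np.ndarray, path: Path) -> None:
    n = xyz.shape[0]
    if n:
        mins = xyz.min(axis=0)
        maxs = xyz.max(axis=0)
    else:
        mins = maxs = np.zeros(3)
    offsets = mins
    header = _LAS_HEADER.pack(
        b"LASF", 0, 0, b"\0" * 16, 1, 2, b"canopyheight".ljust(32, b"\0"),
        b"canopyheight".ljust(32, b"\0"), 0, 0, 227, 227, 0, 0, 20, n,
        n, 0, 0, 0, 0,
        _LAS_SCALE, _LAS_SCALE, _LAS_SCALE,
        offsets[0], offsets[1], offsets[2],
        maxs[0], mins[0], maxs[1], mins[1], maxs[2], mins[2],
    )
    assert len(header) == 227
    scaled = np.round((xyz - offsets) / _LAS_SCALE).astype("<i4")
    rec = np.zeros(n, dtype=[("x", "<i4"), ("y", "<i4"), ("z", "<i4"),
                             ("intensity", "<u2"), ("flags", "u1"),
                             ("classification", "u1"), ("scan_angle", "i1"),
                             ("user", "u1"), ("point_source", "<u2")])
    rec["x"], rec["y"], rec["z"] = scaled[:, 0], scaled[:, 1], scaled[:, 2]
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(rec.tobytes())


def _read_las(path: Path) -> np.ndarray:
    with open(path, "rb") as fh:
        raw = fh.read()
    if raw[:4] != b"LASF":
        raise ValueError(f"{path}: not a LAS file")
    header_size, = struct.unpack_from("<H", raw, 94)
    offset_to_data, = struct.unpack_from("<I", raw, 96)
    point_format, = struct.unpack_from("<B", raw, 104)
    record_len, = struct.unpack_from("<H", raw, 105)
    n, = struct.unpack_from("<I", raw, 107)
    if point_format != 0:
        raise ValueError(f"{path}: only LAS point format 0 supported, got {point_format}")
    scales = struct.unpack_from("<3d", raw, 131)
    offs = struct.unpack_from("<3d", raw, 155)
    rec = np.frombuffer(raw, dtype=[("x", "<i4"), ("y", "<i4"), ("z", "<i4"),
                                    ("rest", f"V{record_len - 12}")],
                        count=n, offset=offset_to_data)
    xyz = np.column_stack([
        rec["x"] * scales[0] + offs[0],
        rec["y"] * scales[1] + offs[1],
        rec["z"] * scales[2] + offs[2],
    ])
    return xyz


# ---------------------------------------------------------------------------
# DSM rasters
# ---------------------------------------------------------------------------

def write_asc(dsm: DSM, path) -> None:
    """Write a DSM as an ESRI ASCII grid (row order: north/top first)."""
    grid = dsm.grid
    values = np.where(dsm.mask, _ASC_NODATA, dsm.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_xy[0]:.6f}\n")
        fh.write(f"yllcorner {grid.origin_xy[1]:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {_ASC_NODATA:g}\n")
        for row in values[::-1]:  # top row first
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_asc(path, aggregator: str = "max") -> DSM:
    """Read an ESRI ASCII grid back into a DSM (aggregator tag supplied)."""
    with open(path) as fh:
        head = {}
        for _ in range(6):
            key, val = fh.readline().split()
            head[key.lower()] = float(val)
        values = np.loadtxt(fh, ndmin=2)[::-1].copy()
    grid = GridSpec(origin_xy=(head["xllcorner"], head["yllcorner"]),
                    cell_size=head["cellsize"], n_cols=int(head["ncols"]),
                    n_rows=int(head["nrows"]))
    mask = values == head["nodata_value"]
    values[mask] = np.nan
    return DSM(values=values, mask=mask, grid=grid, aggregator=aggregator)


def write_geotiff(dsm: DSM, path) -> None:
    """Write a single-band float GeoTIFF (nodata as NaN, plain geotags)."""
    import tifffile

    grid = dsm.grid
    values = np.where(dsm.mask, np.nan, dsm.values).astype(np.float32)[::-1]
    c = grid.cell_size
    y_top = grid.origin_xy[1] + grid.n_rows * c
    extratags = [
        (33550, "d", 3, (c, c, 0.0)),                       # ModelPixelScale
        (33922, "d", 6, (0.0, 0.0, 0.0, grid.origin_xy[0], y_top, 0.0)),
    ]
    tifffile.imwrite(path, values, extratags=extratags)


def read_geotiff(path, aggregator: str = "max") -> DSM:
    """Read a single-band GeoTIFF written by :func:`write_geotiff`."""
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        values = page.asarray()[::-1].astype(float).copy()
        scale = page.tags[33550].value
        tie = page.tags[33922].value
    c = float(scale[0])
    n_rows, n_cols = values.shape
    origin = (float(tie[3]), float(tie[4]) - n_rows * c)
    mask = np.isnan(values)
    grid = GridSpec(origin_xy=origin, cell_size=c, n_cols=n_cols, n_rows=n_rows)
    return DSM(values=values, mask=mask, grid=grid, aggregator=aggregator)
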
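"""Raster layers on a shared geographic grid.

All spatial data in the pipeline lives on a single lon/lat grid described by
a :class:`GridHeader` (ESRI ASCII grid convention: row 0 is the northernmost
row, cells are square, the header stores the lower-left corner). Layers are
exchanged as plain-text ESRI ASCII ``.asc`` files, the format consumed by
MaxEnt-style tools. Cells are half-open intervals ``[west, east) x [south,
north)``; a cell's representative location is its center.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridHeader",
    "Raster",
    "EnvStack",
    "read_ascii_grid",
    "write_ascii_grid",
    "cell_index",
    "extract_values",
]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


class GridError(ValueError):
    """Malformed grid file or misaligned layers."""


@dataclass(frozen=True)
class GridHeader:
    """Geometry shared by all layers of a study region.

    Parameters
    ----------
    ncols, nrows
        Grid dimensions.
    xll, yll
        Longitude/latitude of the lower-left (south-west) corner, degrees.
    cellsize
        Cell edge length in degrees; cells are square.
    nodata
        Sentinel value marking invalid cells in serialized grids.
    """

    ncols: int
    nrows: int
    xll: float
    yll: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.ncols < 1 or self.nrows < 1:
            raise GridError("grid must have at least one row and one column")
        if not self.cellsize > 0:
            raise GridError("cellsize must be positive")
        if self.yll + self.nrows * self.cellsize > 90.0 + 1e-9:
            raise GridError("grid extends beyond the north pole")

    @property
    def xur(self) -> float:
        return self.xll + self.ncols * self.cellsize

    @property
    def yur(self) -> float:
        return self.yll + self.nrows * self.cellsize

    def aligned(self, other: "GridHeader") -> bool:
        """Exact equality of all six geometry fields."""
        return (
            self.ncols == other.ncols
            and self.nrows == other.nrows
            and self.xll == other.xll
            and self.yll == other.yll
            and self.cellsize == other.cellsize
            and self.nodata == other.nodata
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of the center of cell (row, col); row 0 = north."""
        lon = self.xll + (col + 0.5) * self.cellsize
        lat = self.yll + (self.nrows - row - 0.5) * self.cellsize
        return lon, lat

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-cell center coordinates as (lons[nrows,ncols], lats[nrows,ncols])."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        lons = self.xll + (cols + 0.5) * self.cellsize
        lats = self.yll + (self.nrows - rows - 0.5) * self.cellsize
        return np.broadcast_to(lons, (self.nrows, self.ncols)).copy(), np.broadcast_to(
            lats[:, None], (self.nrows, self.ncols)
        ).copy()


@dataclass
class Raster:
    """One environmental layer: values matrix plus validity mask."""

    header: GridHeader
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.header.nrows, self.header.ncols):
            raise GridError(
                f"values shape {self.values.shape} does not match header "
                f"({self.header.nrows}, {self.header.ncols})"
            )
        if self.mask is None:
            self.mask = np.ones_like(self.values, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise GridError("mask shape does not match values")
        # nodata cells are always masked regardless of the supplied mask
        self.mask &= self.values != self.header.nodata
        self.mask &= np.isfinite(self.values)

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None) -> "Raster":
        return Raster(self.header, np.array(values, dtype=float),
                      self.mask.copy() if mask is None else mask)


class EnvStack:
    """Ordered set of grid-aligned rasters keyed by variable name.

    A cell is *jointly valid* iff it is valid in every member layer; all
    sampling, fitting and projection operate on jointly valid cells only.
    """

    def __init__(self, variables: dict[str, Raster]):
        if not variables:
            raise GridError("EnvStack needs at least one layer")
        names = list(variables)
        self.header = variables[names[0]].header
        for name, rast in variables.items():
            if not rast.header.aligned(self.header):
                raise GridError(f"layer {name!r} is not aligned to the stack grid")
        self.variables: dict[str, Raster] = dict(variables)

    @property
    def names(self) -> list[str]:
        return list(self.variables)

    def __getitem__(self, name: str) -> Raster:
        return self.variables[name]

    def __contains__(self, name: str) -> bool:
        return name in self.variables

    def __len__(self) -> int:
        return len(self.variables)

    def joint_mask(self) -> np.ndarray:
        mask = np.ones((self.header.nrows, self.header.ncols), dtype=bool)
        for rast in self.variables.values():
            mask &= rast.mask
        return mask

    def subset(self, names: list[str]) -> "EnvStack":
        missing = [n for n in names if n not in self.variables]
        if missing:
            raise KeyError(f"variables not in stack: {missing}")
        return EnvStack({n: self.variables[n] for n in names})

    def table(self, mask: np.ndarray | None = None) -> pd.DataFrame:
        """Flatten valid cells to a DataFrame (row-major cell order)."""
        m = self.joint_mask() if mask is None else mask
        data = {name: rast.values[m] for name, rast in self.variables.items()}
        rows, cols = np.nonzero(m)
        df = pd.DataFrame(data)
        df.insert(0, "row", rows)
        df.insert(1, "col", cols)
        return df


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid (6-line header + nrows data lines).

    Header keys are case-insensitive; parsing uses the dot decimal separator
    regardless of locale. NoData cells come back masked.
    """
    with open(path, "r") as fh:
        lines = fh.read().splitlines()
    header: dict[str, float] = {}
    for i in range(6):
        if i >= len(lines):
            raise GridError(f"{path}: truncated header at line {i + 1}")
        parts = lines[i].split()
        if len(parts) != 2:
            raise GridError(f"{path}: malformed header line {i + 1}: {lines[i]!r}")
        key = parts[0].lower()
        if key not in _HEADER_KEYS:
            raise GridError(f"{path}: unknown header key {parts[0]!r} at line {i + 1}")
        try:
            header[key] = float(parts[1])
        except ValueError as exc:
            raise GridError(f"{path}: non-numeric header value at line {i + 1}") from exc
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise GridError(f"{path}: missing header keys {missing}")
    hdr = GridHeader(
        ncols=int(header["ncols"]),
        nrows=int(header["nrows"]),
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header["nodata_value"],
    )
    data_lines = [ln for ln in lines[6:] if ln.strip()]
    if len(data_lines) != hdr.nrows:
        raise GridError(
            f"{path}: expected {hdr.nrows} data rows, found {len(data_lines)}"
        )
    rows = []
    for i, ln in enumerate(data_lines):
        toks = ln.split()
        if len(toks) != hdr.ncols:
            raise GridError(
                f"{path}: line {i + 7}: expected {hdr.ncols} values, found {len(toks)}"
            )
        try:
            rows.append([float(t) for t in toks])
        except ValueError as exc:
            raise GridError(f"{path}: non-numeric token at line {i + 7}") from exc
    values = np.array(rows, dtype=float)
    return Raster(hdr, values)


def write_ascii_grid(raster: Raster, path) -> None:
    """Write an ESRI ASCII grid; masked cells become the nodata sentinel.

    Values are serialized with ``repr`` round-trip precision so that
    read-after-write reproduces the matrix bit-for-bit.
    """
    hdr = raster.header
    out = raster.values.copy()
    out[~raster.mask] = hdr.nodata
    with open(path, "w") as fh:
        fh.write(f"ncols {hdr.ncols}\n")
        fh.write(f"nrows {hdr.nrows}\n")
        fh.write(f"xllcorner {_fmt(hdr.xll)}\n")
        fh.write(f"yllcorner {_fmt(hdr.yll)}\n")
        fh.write(f"cellsize {_fmt(hdr.cellsize)}\n")
        fh.write(f"NODATA_value {_fmt(hdr.nodata)}\n")
        for row in out:
            fh.write(" ".join(_fmt(v) for v in row))
            fh.write("\n")


def _fmt(v: float) -> str:
    v = float(v)
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return repr(v)  # shortest string that round-trips the double


def cell_index(lon: float, lat: float, header: GridHeader) -> tuple[int, int]:
    """Map a point to its (row, col) cell under the half-open convention.

    col = floor((lon - xll)/cellsize), row = nrows - 1 - floor((lat - yll)/cellsize).
    Raises ``IndexError`` for out-of-bounds points — the caller decides whether
    to drop the record.
    """
    col = math.floor((lon - header.xll) / header.cellsize)
    row = header.nrows - 1 - math.floor((lat - header.yll) / header.cellsize)
    if not (0 <= col < header.ncols and 0 <= row < header.nrows):
        raise IndexError(f"point ({lon}, {lat}) outside grid bounds")
    return row, col


def cell_index_arrays(
    lons: np.ndarray, lats: np.ndarray, header: GridHeader
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`cell_index`; returns (rows, cols, in_bounds)."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    cols = np.floor((lons - header.xll) / header.cellsize).astype(int)
    rows = header.nrows - 1 - np.floor((lats - header.yll) / header.cellsize).astype(int)
    ok = (cols >= 0) & (cols < header.ncols) & (rows >= 0) & (rows < header.nrows)
    return rows, cols, ok


def extract_values(stack: EnvStack, points) -> pd.DataFrame:
    """Sample every stack layer at a list of (lon, lat) points.

    Returns one row per point with the per-variable values plus a ``valid``
    flag (False at jointly invalid cells); out-of-bounds points raise.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    rows, cols, ok = cell_index_arrays(pts[:, 0], pts[:, 1], stack.header)
    if not ok.all():
        bad = np.nonzero(~ok)[0]
        raise IndexError(f"points out of grid bounds at indices {bad.tolist()}")
    joint = stack.joint_mask()
    data = {"lon": pts[:, 0], "lat": pts[:, 1], "row": rows, "col": cols}
    for name, rast in stack.variables.items():
        data[name] = rast.values[rows, cols]
    df = pd.DataFrame(data)
    df["valid"] = joint[rows, cols]
    return df
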
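"""Aligned multi-layer raster grids and plain-text raster I/O.

Grids are geographic (WGS84 degrees), north-up, square-celled, with
cell-centre registration: row 0 is the northernmost row and all cell <->
coordinate arithmetic is 0-based and half-open.  Rasters are exchanged as
ESRI ASCII grids (``.asc``), a plain-text single-band format readable by any
GIS.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from shapely import contains_xy as _shapely_contains_xy
from shapely.geometry.base import BaseGeometry

NODATA = -9999.0


@dataclass(frozen=True)
class GridTransform:
    """Geo-referencing of a north-up square-celled grid.

    ``origin_lon``/``origin_lat`` locate the *outer corner* of the upper-left
    cell (so the first cell centre is at origin + cell_size/2 in lon, and
    origin - cell_size/2 in lat).
    """

    origin_lon: float
    origin_lat: float
    cell_size: float
    n_rows: int
    n_cols: int

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row, col):
        """(lon, lat) of cell centres for integer row/col (arrays ok)."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.origin_lon + (col + 0.5) * self.cell_size
        lat = self.origin_lat - (row + 0.5) * self.cell_size
        return lon, lat

    def rowcol(self, lon, lat):
        """Integer (row, col) of the cell containing each point (floor rule)."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.origin_lon) / self.cell_size).astype(int)
        row = np.floor((self.origin_lat - lat) / self.cell_size).astype(int)
        return row, col

    def contains_rowcol(self, row, col):
        return (np.asarray(row) >= 0) & (np.asarray(row) < self.n_rows) & \
               (np.asarray(col) >= 0) & (np.asarray(col) < self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.origin_lon + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def lat_centers(self) -> np.ndarray:
        return self.origin_lat - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def center_grids(self):
        """Meshed (lon, lat) arrays of every cell centre, shape (n_rows, n_cols)."""
        lon = np.broadcast_to(self.lon_centers()[None, :], self.shape)
        lat = np.broadcast_to(self.lat_centers()[:, None], self.shape)
        return lon, lat

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(min_lon, min_lat, max_lon, max_lat) outer bounds."""
        return (self.origin_lon,
                self.origin_lat - self.n_rows * self.cell_size,
                self.origin_lon + self.n_cols * self.cell_size,
                self.origin_lat)


class EnvStack:
    """A named stack of aligned single-band layers sharing one nodata mask."""

    def __init__(self, layers: Mapping[str, np.ndarray], transform: GridTransform,
                 nodata_mask: np.ndarray | None = None, set_id: str | None = None):
        if not layers:
            raise ValueError("EnvStack needs at least one layer")
        self.layers: dict[str, np.ndarray] = {}
        for name, arr in layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != transform.shape:
                raise ValueError(
                    f"layer {name!r} shape {arr.shape} != grid shape {transform.shape}")
            self.layers[name] = arr
        self.transform = transform
        if nodata_mask is None:
            nodata_mask = np.zeros(transform.shape, dtype=bool)
        nodata_mask = np.asarray(nodata_mask, dtype=bool)
        if nodata_mask.shape != transform.shape:
            raise ValueError("nodata mask shape mismatch")
        # any NaN in any layer joins the shared mask
        for arr in self.layers.values():
            nodata_mask = nodata_mask | ~np.isfinite(arr)
        self.nodata_mask = nodata_mask
        self.set_id = set_id

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    @property
    def shape(self) -> tuple[int, int]:
        return self.transform.shape

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def array(self, names: Sequence[str] | None = None) -> np.ndarray:
        """Stack layers into an (n_layers, n_rows, n_cols) array."""
        names = list(names) if names is not None else self.names
        return np.stack([self.layers[n] for n in names])

    def valid_values(self, names: Sequence[str] | None = None) -> np.ndarray:
        """(n_valid_cells, n_layers) matrix of values at non-nodata cells."""
        names = list(names) if names is not None else self.names
        ok = ~self.nodata_mask
        return np.column_stack([self.layers[n][ok] for n in names])

    def subset(self, names: Iterable[str], set_id: str | None = None) -> "EnvStack":
        names = list(names)
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return EnvStack({n: self.layers[n] for n in names}, self.transform,
                        self.nodata_mask.copy(), set_id=set_id or self.set_id)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"EnvStack({self.n_layers} layers {self.names}, "
                f"shape={self.shape}, set_id={self.set_id!r})")


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

def write_ascii_grid(path: str | Path, array: np.ndarray, transform: GridTransform,
                     nodata: float = NODATA) -> Path:
    """Write one layer as an ESRI ASCII grid (cells with NaN become nodata)."""
    path = Path(path)
    arr = np.asarray(array, dtype=float)
    if arr.shape != transform.shape:
        raise ValueError("array shape does not match transform")
    xll = transform.origin_lon
    yll = transform.origin_lat - transform.n_rows * transform.cell_size
    out = np.where(np.isfinite(arr), arr, nodata)
    header = (f"ncols {transform.n_cols}\n"
              f"nrows {transform.n_rows}\n"
              f"xllcorner {xll!r}\n"
              f"yllcorner {yll!r}\n"
              f"cellsize {transform.cell_size!r}\n"
              f"NODATA_value {nodata!r}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.10g")
    return path


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridTransform]:
    """Read an ESRI ASCII grid; nodata cells come back as NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            m = re.match(r"\s*(\w+)\s+([-+0-9.eE]+)", line)
            if not m:
                break
            header[m.group(1).lower()] = float(m.group(2))
            pos = fh.tell()
        fh.seek(pos)
        data = np.loadtxt(fh)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        xll, yll = header["xllcorner"], header["yllcorner"]
    else:  # cell-centre variant
        xll = header["xllcenter"] - cell / 2.0
        yll = header["yllcenter"] - cell / 2.0
    data = np.atleast_2d(data).reshape(n_rows, n_cols)
    nodata = header.get("nodata_value", NODATA)
    data = np.where(np.isclose(data, nodata), np.nan, data)
    transform = GridTransform(origin_lon=xll, origin_lat=yll + n_rows * cell,
                              cell_size=cell, n_rows=n_rows, n_cols=n_cols)
    return data, transform


def write_stack(directory: str | Path, stack: EnvStack) -> list[Path]:
    """Write every layer of a stack as ``<directory>/<name>.asc``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in stack.names:
        arr = np.where(stack.nodata_mask, np.nan, stack.layers[name])
        paths.append(write_ascii_grid(directory / f"{name}.asc", arr, stack.transform))
    return paths


def read_stack(directory: str | Path, set_id: str | None = None) -> EnvStack:
    """Read every ``.asc`` in a directory (sorted by name) into a stack."""
    directory = Path(directory)
    files = sorted(directory.glob("*.asc"))
    if not files:
        raise FileNotFoundError(f"no .asc layers under {directory}")
    layers = {}
    transform = None
    for f in files:
        arr, tr = read_ascii_grid(f)
        if transform is None:
            transform = tr
        elif tr != transform:
            raise ValueError(f"layer {f.name} is not aligned with the others")
        layers[f.stem] = arr
    return EnvStack(layers, transform, set_id=set_id)


# ---------------------------------------------------------------------------
# Resampling and masking

def resample_to_grid(raw: EnvStack, target: GridTransform,
                     method: str = "bilinear",
                     categorical: Iterable[str] = ()) -> EnvStack:
    """Resample a stack onto a target grid definition.

    Continuous layers use bilinear interpolation; layers named in
    ``categorical`` (or all layers when ``method == 'nearest'``) use
    nearest-neighbour.  Target cells whose centres fall outside the source
    extent, or that interpolate from nodata, become nodata.
    """
    if method not in ("bilinear", "nearest"):
        raise ValueError(f"unknown method {method!r}")
    src = raw.transform
    smin_lon, smin_lat, smax_lon, smax_lat = src.bounds
    tmin_lon, tmin_lat, tmax_lon, tmax_lat = target.bounds
    if tmin_lon >= smax_lon or tmax_lon <= smin_lon or \
       tmin_lat >= smax_lat or tmax_lat <= smin_lat:
        raise ValueError("target extent is disjoint from the source extent")

    lon, lat = target.center_grids()
    # fractional source index of each target cell centre (0 at first centre)
    col_f = (lon - src.origin_lon) / src.cell_size - 0.5
    row_f = (src.origin_lat - lat) / src.cell_size - 0.5
    inside = (col_f >= -0.5) & (col_f <= src.n_cols - 0.5) & \
             (row_f >= -0.5) & (row_f <= src.n_rows - 0.5)
    coords = np.array([row_f.ravel(), col_f.ravel()])

    categorical = set(categorical)
    layers = {}
    bad = ~inside
    src_nodata = raw.nodata_mask.astype(float)
    # nodata bleeds through interpolation: any weight on a nodata cell kills it
    nod = map_coordinates(src_nodata, coords, order=1, mode="nearest").reshape(target.shape)
    for name, arr in raw.layers.items():
        order = 0 if (method == "nearest" or name in categorical) else 1
        filled = np.where(raw.nodata_mask, 0.0, arr)
        out = map_coordinates(filled, coords, order=order, mode="nearest")
        out = out.reshape(target.shape)
        out[bad | (nod > 1e-9)] = np.nan
        layers[name] = out
    return EnvStack(layers, target, set_id=raw.set_id)


def mask_from_polygon(transform: GridTransform, polygon: BaseGeometry) -> np.ndarray:
    """Boolean grid, True where the cell centre lies inside the polygon."""
    lon, lat = transform.center_grids()
    return _shapely_contains_xy(polygon, np.ascontiguousarray(lon), np.ascontiguousarray(lat))
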
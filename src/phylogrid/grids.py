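"""Geographic grids and raster stacks.

All rasters in the package share a single north-up geographic grid in degree
coordinates.  ``GridSpec`` carries the geotransform: the north-west corner,
a square cell size, and the array shape.  Row 0 is the northernmost row, so
latitude decreases with row index.  Cell membership is half-open: a point
lying exactly on a shared edge belongs to the cell to its south-east.

Rasters are serialized as ESRI ASCII grids (plain-text ``.asc``), which any
GIS reads natively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "RasterStack", "read_ascii_grid", "write_ascii_grid"]

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """North-up geographic grid: NW corner, square cells, shape."""

    x_origin: float  # west edge longitude of the NW corner
    y_origin: float  # north edge latitude of the NW corner
    cell_size: float  # degrees
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row, col):
        """Longitude/latitude of cell centers (vectorized)."""
        row = np.asarray(row)
        col = np.asarray(col)
        lon = self.x_origin + (col + 0.5) * self.cell_size
        lat = self.y_origin - (row + 0.5) * self.cell_size
        return lon, lat

    def point_to_cell(self, lon, lat):
        """Map points to (row, col); half-open edges go south-east."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((self.y_origin - lat) / self.cell_size).astype(int)
        return row, col

    def contains(self, lon, lat):
        row, col = self.point_to_cell(lon, lat)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def coarsen(self, factor: int) -> "GridSpec":
        """Grid of ``factor``-times larger cells covering the same extent."""
        if factor < 1:
            raise ValueError("aggregation factor must be >= 1")
        n_rows = -(-self.n_rows // factor)
        n_cols = -(-self.n_cols // factor)
        return replace(
            self,
            cell_size=self.cell_size * factor,
            n_rows=n_rows,
            n_cols=n_cols,
        )


@dataclass
class RasterStack:
    """Named co-registered 2-D layers on one :class:`GridSpec`."""

    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, arr in self.layers.items():
            self._check(name, arr)

    def _check(self, name: str, arr: np.ndarray) -> None:
        if arr.shape != self.grid.shape:
            raise ValueError(
                f"layer {name!r} has shape {arr.shape}, grid is {self.grid.shape}"
            )

    def add(self, name: str, arr: np.ndarray) -> None:
        arr = np.asarray(arr, dtype=float)
        self._check(name, arr)
        self.layers[name] = arr

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __len__(self) -> int:
        return len(self.layers)

    def values_at(self, lon, lat, names=None):
        """Environment values at point locations, shape (n_points, n_layers).

        Points outside the grid or on missing cells yield NaN rows.
        """
        names = list(names) if names is not None else self.names
        row, col = self.grid.point_to_cell(lon, lat)
        inside = (
            (row >= 0)
            & (row < self.grid.n_rows)
            & (col >= 0)
            & (col < self.grid.n_cols)
        )
        out = np.full((len(np.atleast_1d(row)), len(names)), np.nan)
        r = np.atleast_1d(row)[inside]
        c = np.atleast_1d(col)[inside]
        for j, name in enumerate(names):
            out[inside, j] = self.layers[name][r, c]
        return out

    def table(self, names=None):
        """Flatten layers to an (n_cells, n_layers) matrix (C row order)."""
        names = list(names) if names is not None else self.names
        return np.column_stack([self.layers[n].ravel() for n in names])

    def write_dir(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.layers.items():
            write_ascii_grid(directory / f"{name}.asc", arr, self.grid)

    @classmethod
    def read_dir(cls, directory) -> "RasterStack":
        directory = Path(directory)
        paths = sorted(directory.glob("*.asc"))
        if not paths:
            raise FileNotFoundError(f"no .asc layers found in {directory}")
        grid = None
        layers = {}
        for p in paths:
            arr, g = read_ascii_grid(p)
            if grid is None:
                grid = g
            elif g != grid:
                raise ValueError(f"layer {p.name} is not on the shared grid")
            layers[p.stem] = arr
        return cls(grid=grid, layers=layers)


def write_ascii_grid(path, arr: np.ndarray, grid: GridSpec) -> None:
    """Write a layer as an ESRI ASCII grid (NaN -> nodata)."""
    arr = np.asarray(arr, dtype=float)
    if arr.shape != grid.shape:
        raise ValueError("array shape does not match grid")
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.x_origin!r}\n"
        f"yllcorner {grid.y_origin - grid.n_rows * grid.cell_size!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {NODATA}\n"
    )
    body = np.where(np.isfinite(arr), arr, NODATA)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.10g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"}:
                meta[key] = float(value)
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        arr = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(meta["nrows"]), int(meta["ncols"])
    if arr.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data block shape {arr.shape} does not match header")
    nodata = meta.get("nodata_value", NODATA)
    arr = np.where(arr == nodata, np.nan, arr)
    grid = GridSpec(
        x_origin=meta["xllcorner"],
        y_origin=meta["yllcorner"] + n_rows * meta["cellsize"],
        cell_size=meta["cellsize"],
        n_rows=n_rows,
        n_cols=n_cols,
    )
    return arr, grid
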
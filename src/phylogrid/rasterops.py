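"""From continuous suitability to the coarse presence-absence matrix.

The index layer consumes a species-by-cell binary occupancy at a coarse
grid.  Suitability is aggregated fine-to-coarse by block maximum first, the
maxSSS threshold is applied to the aggregated values, and the resulting
binary maps are cropped to the study region last.  Species that lose every
occupied cell along the way are dropped (and logged) rather than carried as
all-zero columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely

from .grids import GridSpec

__all__ = [
    "PresenceAbsenceMatrix",
    "aggregate_max",
    "threshold_maxsss",
    "binarize",
    "points_to_binary",
    "crop_to_region",
    "build_pam",
]

log = logging.getLogger(__name__)


@dataclass
class PresenceAbsenceMatrix:
    """Binary occupancy of coarse grid cells by species.

    ``matrix`` is (n_cells, n_species) with entries in {0, 1}; ``rows`` and
    ``cols`` give each cell's coarse grid indices.  Only cells inside the
    region of interest are listed; empty cells (no species) are retained so
    that richness-zero cells remain addressable, but index code skips them.
    """

    matrix: np.ndarray
    species: list[str]
    rows: np.ndarray
    cols: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (cells x species)")
        if self.matrix.shape != (len(self.rows), len(self.species)):
            raise ValueError("matrix shape inconsistent with cells/species")
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("matrix entries must be 0/1")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_species(self) -> int:
        return self.matrix.shape[1]

    @property
    def range_sizes(self) -> np.ndarray:
        """Occupied-cell count per species (column sums)."""
        return self.matrix.sum(axis=0).astype(int)

    @property
    def richness(self) -> np.ndarray:
        """Species count per cell (row sums)."""
        return self.matrix.sum(axis=1).astype(int)

    @property
    def cell_ids(self) -> list[str]:
        return [f"r{r}c{c}" for r, c in zip(self.rows, self.cols)]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        return self.grid.cell_center(self.rows, self.cols)

    def drop_empty_species(self) -> "PresenceAbsenceMatrix":
        keep = self.range_sizes > 0
        dropped = [s for s, k in zip(self.species, keep) if not k]
        if dropped:
            log.warning("dropping species with no occupied cells: %s", dropped)
        return PresenceAbsenceMatrix(
            matrix=self.matrix[:, keep],
            species=[s for s, k in zip(self.species, keep) if k],
            rows=self.rows,
            cols=self.cols,
            grid=self.grid,
        )

    def to_frame(self) -> pd.DataFrame:
        lon, lat = self.cell_centers()
        df = pd.DataFrame(self.matrix, columns=self.species)
        df.insert(0, "lat", lat)
        df.insert(0, "lon", lon)
        df.insert(0, "col", self.cols)
        df.insert(0, "row", self.rows)
        df.insert(0, "cell_id", self.cell_ids)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid: GridSpec | None = None) -> "PresenceAbsenceMatrix":
        df = pd.read_csv(path)
        meta = ["cell_id", "row", "col", "lon", "lat"]
        species = [c for c in df.columns if c not in meta]
        if grid is None:
            # reconstruct the coarse grid from cell centers
            cell = _infer_cell_size(df)
            x0 = float((df["lon"] - (df["col"] + 0.5) * cell).iloc[0])
            y0 = float((df["lat"] + (df["row"] + 0.5) * cell).iloc[0])
            grid = GridSpec(
                x_origin=x0,
                y_origin=y0,
                cell_size=cell,
                n_rows=int(df["row"].max()) + 1,
                n_cols=int(df["col"].max()) + 1,
            )
        return cls(
            matrix=df[species].to_numpy(),
            species=species,
            rows=df["row"].to_numpy(),
            cols=df["col"].to_numpy(),
            grid=grid,
        )


def _infer_cell_size(df: pd.DataFrame) -> float:
    for axis, idx in (("lon", "col"), ("lat", "row")):
        d = df[[axis, idx]].drop_duplicates().sort_values(idx)
        if len(d) > 1:
            steps = np.diff(d[axis]) / np.diff(d[idx])
            return float(abs(steps[0]))
    raise ValueError("cannot infer cell size from a single-cell table")


def aggregate_max(fine: np.ndarray, factor: int) -> np.ndarray:
    """Coarsen by taking the maximum over factor x factor blocks.

    Missing (NaN) cells are ignored; an all-missing block stays missing.
    Ragged edge blocks use whatever cells are available.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    fine = np.asarray(fine, dtype=float)
    if factor == 1:
        return fine.copy()
    n_rows, n_cols = fine.shape
    pr = (-n_rows) % factor
    pc = (-n_cols) % factor
    padded = np.pad(fine, ((0, pr), (0, pc)), constant_values=np.nan)
    blocks = padded.reshape(
        padded.shape[0] // factor, factor, padded.shape[1] // factor, factor
    )
    with np.errstate(all="ignore"):
        out = np.nanmax(blocks, axis=(1, 3))
    out[np.all(np.isnan(blocks), axis=(1, 3))] = np.nan
    return out


def threshold_maxsss(presence_scores, background_scores) -> float:
    """Threshold maximizing sensitivity + specificity.

    Candidates are the distinct observed scores; scores >= t count as
    predicted presence.  Ties are broken toward the smallest threshold.
    """
    pres = np.sort(np.asarray(presence_scores, dtype=float))
    bg = np.sort(np.asarray(background_scores, dtype=float))
    if pres.size == 0 or bg.size == 0:
        raise ValueError("presence and background scores must be nonempty")
    cand = np.unique(np.concatenate([pres, bg]))
    sens = 1.0 - np.searchsorted(pres, cand, side="left") / pres.size
    spec = np.searchsorted(bg, cand, side="left") / bg.size
    total = sens + spec
    best = np.flatnonzero(total >= total.max() - 1e-12)[0]
    return float(cand[best])


def binarize(
    coarse: np.ndarray, threshold: float, mask: np.ndarray | None = None
) -> np.ndarray:
    """Presence where suitability >= threshold, inside the mask, not missing."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    coarse = np.asarray(coarse, dtype=float)
    out = np.where(np.isfinite(coarse) & (coarse >= threshold), 1, 0).astype(np.uint8)
    if mask is not None:
        out = out * np.asarray(mask, dtype=np.uint8)
    return out


def points_to_binary(
    lon, lat, grid: GridSpec, mask: np.ndarray | None = None
) -> np.ndarray:
    """Rasterize points to a binary occupancy grid (half-open cell edges)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    row, col = grid.point_to_cell(lon, lat)
    inside = (row >= 0) & (row < grid.n_rows) & (col >= 0) & (col < grid.n_cols)
    out = np.zeros(grid.shape, dtype=np.uint8)
    out[row[inside], col[inside]] = 1
    if mask is not None:
        out = out * np.asarray(mask, dtype=np.uint8)
    if out.sum() == 0:
        raise ValueError("no points fall inside the region")
    return out


def region_mask(grid: GridSpec, polygon) -> np.ndarray:
    """Boolean grid: cell centers inside the polygon (WKT string or geometry)."""
    if isinstance(polygon, str):
        polygon = shapely.from_wkt(polygon)
    rows, cols = np.indices(grid.shape)
    lon, lat = grid.cell_center(rows.ravel(), cols.ravel())
    inside = shapely.contains_xy(polygon, lon, lat)
    return inside.reshape(grid.shape)


def build_pam(
    binary_maps: dict[str, np.ndarray],
    grid: GridSpec,
    mask: np.ndarray | None = None,
) -> PresenceAbsenceMatrix:
    """Stack per-species binary grids into a PAM over the masked cells."""
    if not binary_maps:
        raise ValueError("no species maps given")
    species = list(binary_maps)
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    rows, cols = np.nonzero(mask)
    matrix = np.column_stack(
        [np.asarray(binary_maps[s])[rows, cols] for s in species]
    ).astype(np.uint8)
    pam = PresenceAbsenceMatrix(
        matrix=matrix, species=species, rows=rows, cols=cols, grid=grid
    )
    return pam.drop_empty_species()


def crop_to_region(pam: PresenceAbsenceMatrix, polygon) -> PresenceAbsenceMatrix:
    """Keep cells whose center lies in the polygon; recompute range sizes.

    Range-size weights (WE/PE) downstream are thereby taken on the cropped
    extent.  Species left with no occupied cell are dropped and logged.
    """
    if isinstance(polygon, str):
        polygon = shapely.from_wkt(polygon)
    lon, lat = pam.cell_centers()
    inside = shapely.contains_xy(polygon, lon, lat)
    if not inside.any():
        raise ValueError("polygon does not intersect any PAM cell")
    cropped = PresenceAbsenceMatrix(
        matrix=pam.matrix[inside],
        species=list(pam.species),
        rows=pam.rows[inside],
        cols=pam.cols[inside],
        grid=pam.grid,
    )
    return cropped.drop_empty_species()
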
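"""Grid geometry and raster containers.

All rasters in a run share one :class:`GridSpec`: a regular square grid in
projected metre coordinates, row 0 at the top. Cells are half-open squares

    column c covers x in [x0 + c*s, x0 + (c+1)*s)
    row    r covers y in (y0 - (r+1)*s, y0 - r*s]

so a point on a shared vertical edge belongs to the cell on its right, and a
point on a shared horizontal edge belongs to the cell above. With the default
``cell_size`` of 100 m a cell is one hectare, which makes per-cell person
counts and per-hectare densities numerically identical at native resolution.

GeoTIFF-style I/O goes through :mod:`tifffile` (single-band float64, nodata
-1); the georeference is carried as JSON in the ImageDescription tag.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import tifffile

NODATA = -1.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the analysis grid.

    Parameters
    ----------
    origin_x, origin_y
        Metre coordinates of the top-left corner of cell (0, 0).
    cell_size
        Cell edge in metres (default 100, i.e. one-hectare cells).
    n_rows, n_cols
        Grid dimensions.
    """

    origin_x: float = 0.0
    origin_y: float = 0.0
    cell_size: float = 100.0
    n_rows: int = 360
    n_cols: int = 360

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_of(self, x, y):
        """Map point coordinates to (row, col) under the half-open convention.

        Vectorised; raises ValueError naming offending indices if any point
        falls outside the grid extent.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.cell_size).astype(np.int64)
        # y-intervals are open at the bottom, closed at the top:
        # y0 - (r+1)s < y <= y0 - r*s  <=>  t = (y0 - y)/s in [r, r+1).
        t = (self.origin_y - y) / self.cell_size
        row = np.floor(t).astype(np.int64)
        bad = (col < 0) | (col >= self.n_cols) | (row < 0) | (row >= self.n_rows)
        if np.any(bad):
            idx = np.flatnonzero(np.atleast_1d(bad))[:5]
            raise ValueError(f"points outside grid extent at positions {idx.tolist()}")
        return row, col

    def cell_center(self, row, col):
        """Centre coordinates of cell (row, col)."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(**d)


def write_raster(path, values: np.ndarray, grid: GridSpec) -> None:
    """Write a single-band float64 raster with the grid georeference.

    nodata is -1; NaNs are stored as nodata.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.shape != grid.shape:
        raise ValueError(f"raster shape {arr.shape} does not match grid {grid.shape}")
    arr = np.where(np.isnan(arr), NODATA, arr)
    meta = {"grid": grid.to_dict(), "nodata": NODATA}
    tifffile.imwrite(str(path), arr, description=json.dumps(meta))


def read_raster(path) -> tuple[np.ndarray, GridSpec]:
    """Read a raster written by :func:`write_raster`; nodata becomes NaN."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        arr = page.asarray().astype(np.float64)
        meta = json.loads(page.tags["ImageDescription"].value)
    grid = GridSpec.from_dict(meta["grid"])
    arr = np.where(arr == meta.get("nodata", NODATA), np.nan, arr)
    return arr, grid


def block_sum(values: np.ndarray, k: int) -> np.ndarray:
    """Sum k-by-k blocks; ragged edge rows/columns are dropped. k=1 is identity."""
    if k < 1:
        raise ValueError("block factor k must be >= 1")
    n_rows, n_cols = values.shape
    if k > n_rows or k > n_cols:
        raise ValueError(f"block factor {k} exceeds grid shape {values.shape}")
    if k == 1:
        return values.copy()
    r, c = n_rows // k, n_cols // k
    v = values[: r * k, : c * k]
    return v.reshape(r, k, c, k).sum(axis=(1, 3))


def block_mean_expand(values: np.ndarray, f: int) -> np.ndarray:
    """Average f-by-f blocks and broadcast back to the native grid.

    Edge blocks that do not divide evenly are averaged over the cells they do
    contain (ragged blocks allowed), so the result is exactly block-constant
    at factor f and has the input's shape.
    """
    if f < 1:
        raise ValueError("native factor must be >= 1")
    if f == 1:
        return values.astype(np.float64, copy=True)
    n_rows, n_cols = values.shape
    row_blk = np.arange(n_rows) // f
    col_blk = np.arange(n_cols) // f
    nb_r, nb_c = row_blk[-1] + 1, col_blk[-1] + 1
    flat_blk = (row_blk[:, None] * nb_c + col_blk[None, :]).ravel()
    sums = np.bincount(flat_blk, weights=values.ravel(), minlength=nb_r * nb_c)
    counts = np.bincount(flat_blk, minlength=nb_r * nb_c)
    means = sums / counts
    return means[flat_blk].reshape(n_rows, n_cols)
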
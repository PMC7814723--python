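"""Planar raster grid geometry and plain-text raster I/O.

All layers in a scene live on one shared :class:`GridSpec` — a regular grid in
a planar (metric) coordinate system, row 0 at the top (north). Rasters are
plain ``numpy`` arrays of shape ``(nrows, ncols)``; files use the ESRI
ASCII-grid format so every artifact stays human-readable text.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "write_ascii_grid", "read_ascii_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster: size, resolution and lower-left origin.

    Parameters
    ----------
    nrows, ncols : int
        Grid dimensions; both must be at least 2.
    cell_size : float
        Cell edge length in meters (> 0).
    origin : (float, float)
        ``(x, y)`` of the lower-left corner, meters.
    """

    nrows: int
    ncols: int
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.nrows < 2 or self.ncols < 2:
            raise ValueError("grid must be at least 2x2")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def n_cells(self) -> int:
        return self.nrows * self.ncols

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in meters."""
        x0, y0 = self.origin
        return (x0, y0, x0 + self.ncols * self.cell_size, y0 + self.nrows * self.cell_size)

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def rowcol_to_xy(self, row, col):
        """Cell-center coordinates for (row, col) indices (row 0 = top)."""
        row = np.asarray(row)
        col = np.asarray(col)
        x0, y0 = self.origin
        x = x0 + (col + 0.5) * self.cell_size
        y = y0 + (self.nrows - row - 0.5) * self.cell_size
        return x, y

    def xy_to_rowcol(self, x, y):
        """Indices of the cells containing planar points (x, y).

        Points outside the grid are clipped to the border cell.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.clip(np.floor((x - x0) / self.cell_size).astype(int), 0, self.ncols - 1)
        row = np.clip(
            self.nrows - 1 - np.floor((y - y0) / self.cell_size).astype(int), 0, self.nrows - 1
        )
        return row, col

    def cell_centers(self):
        """Meshgrid of cell-center X and Y, each of shape ``(nrows, ncols)``."""
        rows, cols = np.mgrid[0 : self.nrows, 0 : self.ncols]
        return self.rowcol_to_xy(rows, cols)


def write_ascii_grid(path, array, grid: GridSpec, nodata: float = -9999.0) -> None:
    """Write a raster as an ESRI ASCII grid (text)."""
    arr = np.asarray(array, dtype=float)
    if arr.shape != grid.shape:
        raise ValueError(f"array shape {arr.shape} does not match grid {grid.shape}")
    out = np.where(np.isfinite(arr), arr, nodata)
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.origin[0]:.6f}\n"
        f"yllcorner {grid.origin[1]:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {nodata:.6f}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6g")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; returns ``(array, GridSpec, nodata)``.

    NODATA cells come back as ``np.inf`` is *not* assumed — they are returned
    as ``nan`` so callers decide the sentinel.
    """
    meta = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        data = np.loadtxt(fh)
    grid = GridSpec(
        nrows=int(meta["nrows"]),
        ncols=int(meta["ncols"]),
        cell_size=meta["cellsize"],
        origin=(meta["xllcorner"], meta["yllcorner"]),
    )
    nodata = meta["nodata_value"]
    data = np.where(data == nodata, np.nan, data)
    return data.reshape(grid.shape), grid, nodata
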
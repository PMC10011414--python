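"""Grid geometry and plain-text raster I/O.

All rasters in the package are dense ``numpy`` arrays tied to a :class:`GridSpec`.
The grid is an abstract planar equal-area grid in kilometres: row 0 is the top
row, column 0 the left column, and cell ``(r, c)`` covers the half-open square
``[x0 + c*s, x0 + (c+1)*s) x (y0 - (r+1)*s, y0 - r*s]`` with ``s`` the cell
size.  Rasters are persisted as ESRI ASCII grids (``.asc``), a plain-text
format readable by every GIS.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a rectangular analysis grid.

    Parameters
    ----------
    n_rows, n_cols : int
        Grid dimensions; both at least 1.
    cell_size_km : float
        Side length of the square cells in kilometres (default 1.0, the
        spatial grain of the analysis).
    origin : (float, float)
        ``(x0, y0)``: x of the left edge and y of the *top* edge, in km.
    """

    n_rows: int
    n_cols: int
    cell_size_km: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and one column")
        if not self.cell_size_km > 0:
            raise ValueError("cell_size_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size_km**2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(x, y)`` arrays of shape ``(n_rows, n_cols)`` of cell centres."""
        x0, y0 = self.origin
        s = self.cell_size_km
        x = x0 + (np.arange(self.n_cols) + 0.5) * s
        y = y0 - (np.arange(self.n_rows) + 0.5) * s
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(y[:, None], self.shape).copy()

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to ``(row, col)`` indices (may fall outside)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size_km).astype(int)
        row = np.floor((y0 - y) / self.cell_size_km).astype(int)
        return row, col

    def contains(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)


def write_ascii_grid(path: str | Path, grid: GridSpec, data: np.ndarray,
                     nodata: float = -9999.0, fmt: str = "%.8g") -> None:
    """Write a raster as an ESRI ASCII grid (text)."""
    data = np.asarray(data)
    if data.shape != grid.shape:
        raise ValueError(f"data shape {data.shape} does not match grid {grid.shape}")
    x0, y0 = grid.origin
    yll = y0 - grid.n_rows * grid.cell_size_km
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {x0}\n"
        f"yllcorner {yll}\n"
        f"cellsize {grid.cell_size_km}\n"
        f"NODATA_value {nodata}\n"
    )
    out = data.astype(float).copy()
    out[~np.isfinite(out)] = nodata
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[GridSpec, np.ndarray, float]:
    """Read an ESRI ASCII grid; returns ``(grid, data, nodata)`` with nodata as NaN."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    s = header["cellsize"]
    y0 = header["yllcorner"] + n_rows * s
    grid = GridSpec(n_rows, n_cols, s, (header["xllcorner"], y0))
    data = data.reshape(grid.shape)
    nodata = header.get("nodata_value", -9999.0)
    data[data == nodata] = np.nan
    return grid, data, nodata
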
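"""Raster elevation grids and ESRI ASCII grid I/O.

The grid convention is north-up: row 0 is the northern edge, column 0 the
western edge, and each cell value is the elevation at the cell centre.
``origin`` is the (x, y) map coordinate of the *outer* (north-west) corner of
cell (0, 0), so the centre of cell (row, col) sits at::

    x = origin_x + (col + 0.5) * cell_size
    y = origin_y - (row + 0.5) * cell_size
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["ElevationGrid", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class ElevationGrid:
    """A 2-D elevation raster with square cells and simple georeferencing.

    Parameters
    ----------
    values
        Elevations in metres, shape (nrows, ncols). NaN marks nodata
        internally; ``nodata`` is the sentinel used on disk.
    cell_size
        Cell edge length in metres (> 0, square cells).
    origin
        (x, y) of the outer north-west corner of cell (0, 0).
    nodata
        Value written for missing cells in ESRI ASCII output.
    """

    values: np.ndarray
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.all(np.isfinite(finite)):
            raise ValueError("elevations must be finite or NaN (nodata)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ElevationGrid":
        return ElevationGrid(self.values.copy(), self.cell_size, self.origin, self.nodata)

    def cell_centre(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of the centre of cell (row, col)."""
        x0, y0 = self.origin
        return (x0 + (col + 0.5) * self.cell_size, y0 - (row + 0.5) * self.cell_size)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of all cell centres, each shaped like values."""
        x0, y0 = self.origin
        cols = x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        rows = y0 - (np.arange(self.nrows) + 0.5) * self.cell_size
        return np.meshgrid(cols, rows)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Cell (row, col) containing map point (x, y)."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise IndexError(f"point ({x}, {y}) outside grid")
        return row, col


def write_ascii_grid(grid: ElevationGrid, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc), row-major north to south."""
    path = Path(path)
    vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    x0, y0 = grid.origin
    # ESRI convention anchors the lower-left corner
    yll = y0 - grid.nrows * grid.cell_size
    with path.open("w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {x0!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> ElevationGrid:
    """Read an ESRI ASCII grid (.asc)."""
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with path.open() as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
                       "yllcenter", "cellsize", "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"missing required header field {req!r} in {path}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    values = np.array(" ".join(data_lines).split(), dtype=float)
    if values.size != nrows * ncols:
        raise ValueError(f"expected {nrows * ncols} values, found {values.size} in {path}")
    values = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    if "xllcorner" in header:
        xll = header["xllcorner"]
    else:  # centre-anchored dialect
        xll = header.get("xllcenter", 0.0) - cell / 2
    if "yllcorner" in header:
        yll = header["yllcorner"]
    else:
        yll = header.get("yllcenter", 0.0) - cell / 2
    origin = (xll, yll + nrows * cell)
    return ElevationGrid(values, cell, origin, nodata)
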
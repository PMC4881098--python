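"""Raster container and ESRI ASCII grid I/O.

A :class:`DEMGrid` is a plain row-major elevation array plus the cell
geometry needed to place it in a projected CRS (origin at the top-left
corner, square cells, meters). Residential masks reuse the same
container with 0/1 values. Rasters are exchanged as ESRI ASCII grids —
a self-describing text format every GIS reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from topoepi.errors import ConfigError, DataError


@dataclass
class DEMGrid:
    """Elevation (or mask) raster with cell geometry.

    Attributes
    ----------
    values : (rows, cols) float ndarray
        Cell values; ``nodata`` marks missing cells.
    cell_size_m : float
        Cell edge length, meters (projected CRS).
    origin : (float, float)
        (x, y) of the **top-left corner** of the grid.
    nodata : float
        Sentinel for missing cells.
    crs_note : str
        Identifier of the projected CRS the coordinates live in.
    """

    values: np.ndarray
    cell_size_m: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0
    crs_note: str = "local-projected-meters"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("raster values must be a 2-D array")
        if self.cell_size_m <= 0:
            raise ConfigError("cell_size_m must be positive")
        valid = self.values != self.nodata
        if not np.all(np.isfinite(self.values[valid])):
            raise DataError("raster contains non-finite values outside nodata")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask_valid(self) -> np.ndarray:
        """Boolean array, True where the cell holds data."""
        return self.values != self.nodata

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of every cell centre, row-major.

        Row 0 is the northernmost row, so y decreases with row index.
        """
        rows, cols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(cols) + 0.5) * self.cell_size_m
        ys = y0 - (np.arange(rows) + 0.5) * self.cell_size_m
        xx, yy = np.meshgrid(xs, ys)
        return xx, yy

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size_m / 1000.0) ** 2

    def same_geometry(self, other: "DEMGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size_m, other.cell_size_m)
            and np.allclose(self.origin, other.origin)
        )


# A residential mask is a DEMGrid whose values are 0/1.
ResidentialMask = DEMGrid


def write_ascii_grid(grid: DEMGrid, path: str | Path, fmt: str = "%.3f") -> None:
    """Write the raster as an ESRI ASCII grid (.asc)."""
    rows, cols = grid.shape
    x0, y0 = grid.origin
    yll = y0 - rows * grid.cell_size_m
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {x0:.6f}\n"
        f"yllcorner {yll:.6f}\n"
        f"cellsize {grid.cell_size_m:.6f}\n"
        f"NODATA_value {grid.nodata:g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, grid.values, fmt=fmt)


def read_ascii_grid(path: str | Path, crs_note: str = "local-projected-meters") -> DEMGrid:
    """Read an ESRI ASCII grid (.asc) into a :class:`DEMGrid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols",
                "nrows",
                "xllcorner",
                "yllcorner",
                "xllcenter",
                "yllcenter",
                "cellsize",
                "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                fh.seek(pos)
                break
        values = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise DataError(f"ASCII grid {path} missing header field {key}")
    rows, cols = int(header["nrows"]), int(header["ncols"])
    if values.shape != (rows, cols):
        raise DataError(
            f"ASCII grid {path}: data shape {values.shape} does not match "
            f"header ({rows}, {cols})"
        )
    cell = header["cellsize"]
    # llcenter variants shift by half a cell to the corner convention
    xll = header.get("xllcorner", header.get("xllcenter", 0.0) - cell / 2)
    yll = header.get("yllcorner", header.get("yllcenter", 0.0) - cell / 2)
    nodata = header.get("nodata_value", -9999.0)
    origin = (xll, yll + rows * cell)
    return DEMGrid(
        values=values,
        cell_size_m=cell,
        origin=origin,
        nodata=nodata,
        crs_note=crs_note,
    )
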
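"""Minimal ESRI ASCII grid raster container and I/O.

Grids are stored row-major from the top (north) row down, in WGS-84 decimal
degrees, matching the ESRI ``.asc`` convention (``ncols/nrows/xllcorner/
yllcorner/cellsize/NODATA_value`` header).  Values are kept in a masked
float array; masked cells are NODATA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class Grid:
    """Gridded surface with cell geometry (lower-left corner registration)."""

    values: np.ma.MaskedArray  # (nrows, ncols), row 0 = northernmost
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0
    crs: str = "WGS-84"

    def __post_init__(self):
        v = np.ma.masked_invalid(np.ma.asarray(self.values, dtype=float))
        if v.ndim != 2:
            raise ValueError("grid values must be 2-D")
        self.values = v

    @property
    def shape(self):
        return self.values.shape

    def cell_centers(self):
        """(lon, lat) arrays of cell centers, each shaped like the grid."""
        nrows, ncols = self.shape
        lon = self.xllcorner + (np.arange(ncols) + 0.5) * self.cellsize
        lat = self.yllcorner + (nrows - np.arange(nrows) - 0.5) * self.cellsize
        return np.meshgrid(lon, lat)

    def contains(self, lon, lat) -> bool:
        nrows, ncols = self.shape
        return (
            self.xllcorner <= lon <= self.xllcorner + ncols * self.cellsize
            and self.yllcorner <= lat <= self.yllcorner + nrows * self.cellsize
        )

    def value_at(self, lon, lat):
        """Value of the cell containing (lon, lat); masked -> None."""
        nrows, ncols = self.shape
        col = int((lon - self.xllcorner) / self.cellsize)
        row = int(nrows - 1 - (lat - self.yllcorner) / self.cellsize)
        if not (0 <= row < nrows and 0 <= col < ncols):
            raise ValueError(f"point ({lon}, {lat}) outside raster extent")
        v = self.values[row, col]
        return None if np.ma.is_masked(v) else float(v)

    def same_geometry(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.xllcorner, other.xllcorner)
            and np.isclose(self.yllcorner, other.yllcorner)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def copy_with(self, values) -> "Grid":
        return Grid(values, self.xllcorner, self.yllcorner, self.cellsize, self.nodata, self.crs)


def read_ascii_grid(path) -> Grid:
    header = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
            "nodata_value", "xllcenter", "yllcenter",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cellsize = header["cellsize"]
    # center registration -> corner registration
    xll = header.get("xllcorner", header.get("xllcenter", 0.0) - cellsize / 2)
    yll = header.get("yllcorner", header.get("yllcenter", 0.0) - cellsize / 2)
    nodata = header.get("nodata_value", -9999.0)
    data = np.array(" ".join(lines[i:]).split(), dtype=float)
    if data.size != nrows * ncols:
        raise ValueError(f"{path}: expected {nrows * ncols} values, got {data.size}")
    values = np.ma.masked_equal(data.reshape(nrows, ncols), nodata)
    return Grid(values, xll, yll, cellsize, nodata)


def write_ascii_grid(grid: Grid, path) -> None:
    filled = grid.values.filled(grid.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.shape[1]}\n")
        fh.write(f"nrows {grid.shape[0]}\n")
        fh.write(f"xllcorner {grid.xllcorner:.10g}\n")
        fh.write(f"yllcorner {grid.yllcorner:.10g}\n")
        fh.write(f"cellsize {grid.cellsize:.10g}\n")
        fh.write(f"NODATA_value {grid.nodata:.10g}\n")
        for row in filled:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
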
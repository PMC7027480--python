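"""Georeferenced raster grids and ESRI ASCII grid I/O.

Grids are north-up, row-major: row 0 is the northern edge, columns run
west to east.  Missing cells are NaN in memory and the ``nodata``
sentinel on disk.  Coordinates refer to cell centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

DEFAULT_NODATA = -9999.0


@dataclass
class RasterGrid:
    """A rectangular 2-D field with square cells.

    ``origin`` is the (x, y) of the lower-left cell *corner* (the ESRI
    ASCII ``xllcorner``/``yllcorner`` convention).
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def like(self, values: np.ndarray) -> "RasterGrid":
        """New grid with this geometry and the given values."""
        if values.shape != self.shape:
            raise ValueError("values shape does not match grid")
        return RasterGrid(values, self.cell_size, self.origin, self.nodata)

    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-NaN) cells."""
        return np.isfinite(self.values)


def check_aligned(*grids: RasterGrid) -> None:
    """Raise unless every grid shares the first grid's geometry."""
    ref = grids[0]
    for i, g in enumerate(grids[1:], start=1):
        if not ref.same_geometry(g):
            raise ValueError(f"raster {i} geometry mismatch: {g.shape} vs {ref.shape}")


def read_esri_ascii(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols", "nrows", "xllcorner", "yllcorner",
            "xllcenter", "yllcenter", "cellsize", "nodata_value",
        ):
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing required header field {key!r}")
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        origin = (header["xllcorner"], header["yllcorner"])
    elif "xllcenter" in header:
        origin = (header["xllcenter"] - cell / 2, header["yllcenter"] - cell / 2)
    else:
        origin = (0.0, 0.0)
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    data = np.loadtxt(lines[n_header:], dtype=float)
    data = np.atleast_2d(data)
    if data.shape != (nrows, ncols):
        data = data.reshape(nrows, ncols)
    values = np.where(data == nodata, np.nan, data)
    return RasterGrid(values, cell, origin, nodata)


def write_esri_ascii(grid: RasterGrid, path: str | Path, fmt: str = "%.6g") -> None:
    """Write a grid as ESRI ASCII; NaN cells become the nodata sentinel."""
    path = Path(path)
    nrows, ncols = grid.shape
    out = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.origin[0]:.6f}\n")
        fh.write(f"yllcorner {grid.origin[1]:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {grid.nodata:g}\n")
        np.savetxt(fh, out, fmt=fmt)
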
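"""Minimal planar raster container and plain-text grid I/O.

Grids are row-major numpy arrays with row 0 at the *north* edge (the usual
raster convention), a square cell size in metres, and a planar origin at the
lower-left corner. Persistence uses the ESRI ASCII grid format (``.asc``), a
plain-text interchange format every desktop GIS reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]

DEFAULT_NODATA = -9999.0


@dataclass
class Raster:
    """A single-band planar grid.

    Parameters
    ----------
    values
        2-D float array, row 0 = northern edge.
    cell_size
        Square cell edge length in metres.
    origin
        (x, y) planar coordinates of the lower-left corner.
    nodata
        Sentinel marking invalid cells.
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

    def valid_mask(self) -> np.ndarray:
        """Boolean grid of cells that are neither nodata nor NaN."""
        return ~(np.isnan(self.values) | (self.values == self.nodata))

    def masked(self) -> np.ndarray:
        """Values with nodata cells replaced by NaN (for arithmetic)."""
        out = self.values.copy()
        out[~self.valid_mask()] = np.nan
        return out

    def like(self, values: np.ndarray, **overrides) -> "Raster":
        """A raster sharing this one's georeferencing with new values.

        NaNs in ``values`` are stored as the nodata sentinel.
        """
        values = np.asarray(values, dtype=float).copy()
        values[np.isnan(values)] = overrides.get("nodata", self.nodata)
        out = replace(self, values=values)
        for key, val in overrides.items():
            setattr(out, key, val)
        return out


def write_ascii_grid(raster: Raster, path) -> None:
    """Write a raster as an ESRI ASCII grid (text)."""
    rows, cols = raster.shape
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {raster.origin[0]:.6f}\n"
        f"yllcorner {raster.origin[1]:.6f}\n"
        f"cellsize {raster.cell_size:.6f}\n"
        f"NODATA_value {raster.nodata:.6f}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster.values, fmt="%.6f")


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = np.atleast_2d(values)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape mismatch in {path}")
    return Raster(
        values=values,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        nodata=header.get("nodata_value", DEFAULT_NODATA),
    )
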
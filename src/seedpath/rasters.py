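"""Minimal single-band raster container with ESRI ASCII grid I/O.

Rasters here live on an abstract projected metric plane (units of metres).
The ASCII grid (.asc) format is plain text and round-trips exactly for the
moderate grid sizes this package works with.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class Raster:
    """Single-band raster: row 0 is the *top* row (north-up convention)."""

    values: np.ndarray  # 2-D float array, NaN = nodata
    xllcorner: float
    yllcorner: float
    cellsize: float
    crs: str = "local-metric"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        nrow, ncol = self.values.shape
        return (
            self.xllcorner,
            self.yllcorner,
            self.xllcorner + ncol * self.cellsize,
            self.yllcorner + nrow * self.cellsize,
        )

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays of pixel centers, same shape as values."""
        nrow, ncol = self.values.shape
        xs = self.xllcorner + (np.arange(ncol) + 0.5) * self.cellsize
        ys = self.yllcorner + (nrow - np.arange(nrow) - 0.5) * self.cellsize
        return np.meshgrid(xs, ys)


def write_ascii_grid(raster: Raster, path: str | Path, nodata: float = -9999.0) -> None:
    vals = np.where(np.isnan(raster.values), nodata, raster.values)
    nrow, ncol = vals.shape
    header = (
        f"ncols {ncol}\nnrows {nrow}\n"
        f"xllcorner {raster.xllcorner!r}\nyllcorner {raster.yllcorner!r}\n"
        f"cellsize {raster.cellsize!r}\nNODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> Raster:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, val = line.split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)
    nodata = header.get("nodata_value", -9999.0)
    vals = np.where(vals == nodata, np.nan, vals)
    return Raster(
        values=vals,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
    )
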
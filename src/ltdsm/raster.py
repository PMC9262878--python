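"""Minimal regular-grid raster with plain-text (ESRI ASCII grid) I/O.

Grids are stored as float arrays with NaN for no-data, row 0 at the
northern edge (the ASCII-grid convention).  Coordinates are projected
kilometres; the cell centre of (row r, col c) is
x = xll + (c + 0.5) h,  y = yll + (nrows - r - 0.5) h.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class Raster:
    data: np.ndarray  # (nrows, ncols), NaN = no-data
    xll: float  # x of lower-left corner
    yll: float  # y of lower-left corner
    cellsize: float
    name: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")
        if not self.cellsize > 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self):
        return self.data.shape

    def cell_centres(self):
        """(X, Y) meshgrids of cell-centre coordinates."""
        nr, nc = self.data.shape
        xs = self.xll + (np.arange(nc) + 0.5) * self.cellsize
        ys = self.yll + (nr - np.arange(nr) - 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    def sample_bilinear(self, x, y):
        """Bilinear interpolation at points; NaN outside or on no-data."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        nr, nc = self.data.shape
        h = self.cellsize
        # fractional index of the cell-centre lattice
        fc = (x - self.xll) / h - 0.5
        fr = (self.yll + nr * h - y) / h - 0.5
        out = np.full(x.shape, np.nan)
        c0 = np.floor(fc).astype(int)
        r0 = np.floor(fr).astype(int)
        ok = (c0 >= 0) & (c0 + 1 <= nc - 1) & (r0 >= 0) & (r0 + 1 <= nr - 1)
        if np.any(ok):
            c0o, r0o = c0[ok], r0[ok]
            tx = fc[ok] - c0o
            ty = fr[ok] - r0o
            z00 = self.data[r0o, c0o]
            z01 = self.data[r0o, c0o + 1]
            z10 = self.data[r0o + 1, c0o]
            z11 = self.data[r0o + 1, c0o + 1]
            val = (
                z00 * (1 - tx) * (1 - ty)
                + z01 * tx * (1 - ty)
                + z10 * (1 - tx) * ty
                + z11 * tx * ty
            )
            out[ok] = val
        return out if out.size > 1 else float(out[0])


def write_ascii_grid(raster: Raster, path) -> None:
    nr, nc = raster.data.shape
    nodata = -9999.0
    body = np.where(np.isfinite(raster.data), raster.data, nodata)
    with open(path, "w") as fh:
        fh.write(
            f"ncols {nc}\nnrows {nr}\n"
            f"xllcorner {raster.xll}\nyllcorner {raster.yll}\n"
            f"cellsize {raster.cellsize}\nNODATA_value {nodata}\n"
        )
        for row in body:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_ascii_grid(path, name: str = "") -> Raster:
    path = Path(path)
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    for line in lines[:6]:
        k, v = line.split()
        header[k.lower()] = float(v)
    data = np.loadtxt(lines[6:])
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value", -9999.0)
    data = np.where(data == nodata, np.nan, data)
    return Raster(
        data,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        name=name or path.stem,
    )
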
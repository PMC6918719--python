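"""Minimal single-band raster container with ESRI ASCII grid I/O.

Coordinates are planar metric (x east, y north). Row 0 of ``data`` is the
*northernmost* row, matching the ESRI ASCII layout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["Raster", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class Raster:
    data: np.ndarray          # (nrows, ncols), row 0 = north
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered extent."""
        return (
            self.xllcorner,
            self.yllcorner,
            self.xllcorner + self.ncols * self.cellsize,
            self.yllcorner + self.nrows * self.cellsize,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.yllcorner + (np.arange(self.nrows)[::-1] + 0.5) * self.cellsize
        return xs, ys

    def sample_bilinear(self, x, y) -> np.ndarray:
        """Bilinearly interpolated values at points (x, y).

        Points are interpolated between cell centers; outside the center
        lattice the nearest-cell value is used (clamped), so any point inside
        the raster extent gets a finite value.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        # fractional column/row in cell-center coordinates
        fc = (x - self.xllcorner) / self.cellsize - 0.5
        # row 0 is the north edge
        fr = (self.yllcorner + self.nrows * self.cellsize - y) / self.cellsize - 0.5
        fc = np.clip(fc, 0.0, self.ncols - 1.0)
        fr = np.clip(fr, 0.0, self.nrows - 1.0)
        c0 = np.floor(fc).astype(int)
        r0 = np.floor(fr).astype(int)
        c1 = np.minimum(c0 + 1, self.ncols - 1)
        r1 = np.minimum(r0 + 1, self.nrows - 1)
        tc = fc - c0
        tr = fr - r0
        z = (
            self.data[r0, c0] * (1 - tr) * (1 - tc)
            + self.data[r0, c1] * (1 - tr) * tc
            + self.data[r1, c0] * tr * (1 - tc)
            + self.data[r1, c1] * tr * tc
        )
        return z


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"ncols {raster.ncols}\n")
        fh.write(f"nrows {raster.nrows}\n")
        fh.write(f"xllcorner {raster.xllcorner:.6f}\n")
        fh.write(f"yllcorner {raster.yllcorner:.6f}\n")
        fh.write(f"cellsize {raster.cellsize:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata}\n")
        np.savetxt(fh, raster.data, fmt="%.4f")


def read_ascii_grid(path: str | Path) -> Raster:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            key, _, value = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                header[key] = float(value)
            else:  # header shorter than 6 lines
                fh.seek(pos)
                break
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    return Raster(
        data=data,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )
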
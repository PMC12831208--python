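"""Gridded raster container and raster-level operations.

A :class:`Raster` is a rectangular grid of cell values on a regular lattice.
Row 0 is the southernmost row (y increases with row index); cell (row, col)
has its center at ``origin + (col + 0.5, row + 0.5) * cell_size``. Two
coordinate modes are supported: ``planar_km`` (x, y in kilometres, Euclidean
distances) and ``lonlat`` (degrees, great-circle distances).

On-disk format is the plain-text ESRI ASCII grid (.asc), which stores the
lower-left corner, cell size and a NODATA sentinel and writes rows
north-to-south.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

_EARTH_RADIUS_KM = 6371.0


@dataclass
class Raster:
    """Regular grid of values with lower-left origin georeferencing.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values; NaN marks missing cells. Row 0 is the southernmost row.
    origin : (float, float)
        Coordinates (x, y) of the lower-left corner of the grid.
    cell_size : float
        Cell edge length (km in ``planar_km`` mode, degrees in ``lonlat``).
    crs_mode : {"planar_km", "lonlat"}
        Distance model used by buffer extraction.
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 1.0
    crs_mode: str = "planar_km"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.crs_mode not in ("planar_km", "lonlat"):
            raise ValueError(f"unknown crs_mode {self.crs_mode!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        nrows, ncols = self.values.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + ncols * self.cell_size, y0 + nrows * self.cell_size)

    def x_centers(self) -> np.ndarray:
        ncols = self.values.shape[1]
        return self.origin[0] + (np.arange(ncols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        nrows = self.values.shape[0]
        return self.origin[1] + (np.arange(nrows) + 0.5) * self.cell_size

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x <= xmax and ymin <= y <= ymax

    def cell_index(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing a point (clipped to the grid edge)."""
        if not self.contains(x, y):
            raise ValueError(f"point ({x}, {y}) outside raster extent {self.extent}")
        nrows, ncols = self.values.shape
        col = min(int((x - self.origin[0]) / self.cell_size), ncols - 1)
        row = min(int((y - self.origin[1]) / self.cell_size), nrows - 1)
        return row, col

    def value_at(self, x: float, y: float) -> float:
        row, col = self.cell_index(x, y)
        return float(self.values[row, col])

    def aligned_with(self, other: "Raster") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.origin, other.origin)
            and np.isclose(self.cell_size, other.cell_size)
            and self.crs_mode == other.crs_mode
        )

    def copy_with(self, values: np.ndarray) -> "Raster":
        return replace(self, values=np.asarray(values, dtype=float))

    # --- ESRI ASCII grid I/O -------------------------------------------------

    def to_ascii(self, path: str | Path, nodata: float = -9999.0) -> None:
        vals = self.values.copy()
        vals[~np.isfinite(vals)] = nodata
        nrows, ncols = vals.shape
        header = (
            f"ncols {ncols}\n"
            f"nrows {nrows}\n"
            f"xllcorner {self.origin[0]!r}\n"
            f"yllcorner {self.origin[1]!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {nodata!r}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals[::-1], fmt="%.10g")  # rows north-to-south

    @classmethod
    def from_ascii(cls, path: str | Path, crs_mode: str = "planar_km") -> "Raster":
        meta: dict[str, float] = {}
        with open(path) as fh:
            lines = fh.readlines()
        n_header = 0
        for line in lines:
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                meta[parts[0].lower()] = float(parts[1])
                n_header += 1
            else:
                break
        vals = np.loadtxt(lines[n_header:], ndmin=2)[::-1].copy()
        nodata = meta.get("nodata_value")
        if nodata is not None:
            vals[vals == nodata] = np.nan
        return cls(
            values=vals,
            origin=(meta.get("xllcorner", 0.0), meta.get("yllcorner", 0.0)),
            cell_size=meta.get("cellsize", 1.0),
            crs_mode=crs_mode,
        )


def validate_concentration(raster: Raster) -> Raster:
    """Check a concentration raster holds strictly positive finite values."""
    vals = raster.values
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite <= 0).any():
        raise ValueError("concentration raster contains non-positive values")
    return raster


def validate_settlement(raster: Raster) -> Raster:
    """Check a settlement raster holds integer classes 1..7."""
    vals = raster.values[np.isfinite(raster.values)]
    if not np.all(np.isin(vals, np.arange(1, 8))):
        raise ValueError("settlement raster classes must be integers in 1..7")
    return raster


def annual_mean(daily_rasters: Sequence[Raster] | Iterable[Raster]) -> Raster:
    """Cell-wise arithmetic mean over aligned rasters, ignoring missing cells.

    Cells that are missing on every input raster stay missing in the output.
    Rasters must share shape, origin, cell size and coordinate mode.
    """
    rasters = list(daily_rasters)
    if not rasters:
        raise ValueError("at least one raster is required")
    first = rasters[0]
    for r in rasters[1:]:
        if not first.aligned_with(r):
            raise ValueError("rasters are not aligned (shape/origin/cell_size/crs)")
    stack = np.stack([r.values for r in rasters])
    with warnings.catch_warnings():
        # cells missing on every day legitimately yield NaN
        warnings.simplefilter("ignore", RuntimeWarning)
        out = np.nanmean(stack, axis=0)
    return first.copy_with(out)


def pairwise_distances(
    raster: Raster, x: float, y: float, xs: np.ndarray, ys: np.ndarray
) -> np.ndarray:
    """Distances (km) from (x, y) to coordinate arrays under the raster's mode."""
    if raster.crs_mode == "planar_km":
        return np.hypot(xs - x, ys - y)
    lon1, lat1 = np.radians(x), np.radians(y)
    lon2, lat2 = np.radians(xs), np.radians(ys)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * _EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
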
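"""Raster surfaces for landscape analysis.

A :class:`GridSurface` is a rectangular grid of real values with a cell size
in meters, a top-left origin, and an optional nodata mask.  Row 0 is the
northernmost row; cells are addressed ``(row, col)`` and cover half-open
intervals ``[origin, origin + n * cell_size)`` in map coordinates.

Surfaces are read and written as ESRI ASCII grids, the plain-text raster
interchange format understood by every GIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridSurface",
    "SamplePoints",
    "read_ascii_grid",
    "write_ascii_grid",
    "compute_ndvi",
    "reclassify_binary",
    "resample",
]


@dataclass
class GridSurface:
    """A single-band raster with planar-meter georeferencing.

    Parameters
    ----------
    values : ndarray of shape (n_rows, n_cols)
        Cell values; row 0 is the northernmost row.
    cell_size : float
        Cell edge length in meters (> 0).
    origin : tuple of float
        Map coordinates (x, y) of the *top-left corner* of cell (0, 0).
    mask : ndarray of bool, optional
        True where a cell is nodata.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.mask is None:
            self.mask = ~np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values shape")
            self.mask = self.mask | ~np.isfinite(self.values)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def unmasked(self) -> np.ndarray:
        """Return the 1-D array of valid (non-nodata) cell values."""
        return self.values[~self.mask]

    def copy_with(self, values: np.ndarray, mask: np.ndarray | None = None) -> "GridSurface":
        """New surface with the same geometry but different values."""
        return GridSurface(
            values=np.asarray(values, dtype=float),
            cell_size=self.cell_size,
            origin=self.origin,
            mask=self.mask.copy() if mask is None else mask,
        )

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        """Cell (row, col) containing map point (x, y).

        Cells are half-open, so a point exactly on the shared edge of two
        cells belongs to the cell to the south-east of the edge.
        """
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"point ({x}, {y}) falls outside the grid")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        return (
            x0 + (col + 0.5) * self.cell_size,
            y0 - (row + 0.5) * self.cell_size,
        )


@dataclass
class SamplePoints:
    """Point measurements (x, y, value) used for spatial interpolation."""

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.x.shape == self.y.shape == self.values.shape):
            raise ValueError("x, y, value arrays must have equal length")

    def __len__(self) -> int:
        return self.x.size

    @classmethod
    def from_csv(cls, path) -> "SamplePoints":
        df = pd.read_csv(path)
        for col in ("x", "y", "value"):
            if col not in df.columns:
                raise ValueError(f"point CSV must have column '{col}'")
        return cls(df["x"].to_numpy(), df["y"].to_numpy(), df["value"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame({"x": self.x, "y": self.y, "value": self.values}).to_csv(
            path, index=False
        )


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_NODATA = -9999.0


def write_ascii_grid(surface: GridSurface, path) -> None:
    """Write a surface as an ESRI ASCII grid (.asc)."""
    vals = surface.values.copy()
    vals[surface.mask] = _NODATA
    x0, y0 = surface.origin
    yll = y0 - surface.n_rows * surface.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {surface.n_cols}\n")
        fh.write(f"nrows {surface.n_rows}\n")
        fh.write(f"xllcorner {x0:.17g}\n")
        fh.write(f"yllcorner {yll:.17g}\n")
        fh.write(f"cellsize {surface.cell_size:.17g}\n")
        fh.write(f"NODATA_value {_NODATA:.17g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_ascii_grid(path) -> GridSurface:
    """Read an ESRI ASCII grid (.asc) into a :class:`GridSurface`."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(p) for p in parts])
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"ASCII grid missing header field '{req}'")
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid data block does not match declared shape")
    nodata = header.get("nodata_value")
    mask = np.zeros_like(values, dtype=bool)
    if nodata is not None:
        mask = values == nodata
        values = np.where(mask, np.nan, values)
    y0 = header["yllcorner"] + header["nrows"] * header["cellsize"]
    return GridSurface(
        values=values,
        cell_size=header["cellsize"],
        origin=(header["xllcorner"], y0),
        mask=mask,
    )


# ---------------------------------------------------------------------------
# Derived surfaces


def compute_ndvi(red: GridSurface, nir: GridSurface) -> GridSurface:
    """Normalized difference vegetation index, (NIR - Red) / (NIR + Red).

    Cells where the band sum is zero (no reflectance information) are
    masked.  Any cell masked in either input band is masked in the output.
    """
    if red.shape != nir.shape:
        raise ValueError(
            f"band shapes differ: red {red.shape} vs nir {nir.shape}"
        )
    if red.cell_size != nir.cell_size:
        raise ValueError("band cell sizes differ")
    total = nir.values + red.values
    mask = red.mask | nir.mask | (total == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ndvi = (nir.values - red.values) / total
    ndvi = np.where(mask, np.nan, ndvi)
    return GridSurface(ndvi, red.cell_size, red.origin, mask=mask)


def reclassify_binary(surface: GridSurface, threshold: float) -> GridSurface:
    """Presence/absence reclassification: 1 where value >= threshold, else 0.

    Used to derive the binary vegetation "Feature" surface from NDVI; bare
    soil and rock typically show NDVI below about 0.1.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    out = (surface.values >= threshold).astype(float)
    out = np.where(surface.mask, np.nan, out)
    return surface.copy_with(out)


def resample(surface: GridSurface, cell_size: float, categorical: bool = False) -> GridSurface:
    """Resample to a new resolution.

    Continuous surfaces are interpolated bilinearly; categorical (e.g.
    binary presence/absence) surfaces take the majority value of the
    covering source cells.  The output covers the same extent.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    height = surface.n_rows * surface.cell_size
    width = surface.n_cols * surface.cell_size
    n_rows = max(1, int(round(height / cell_size)))
    n_cols = max(1, int(round(width / cell_size)))
    x0, y0 = surface.origin

    # target cell centers in source fractional index space
    xc = x0 + (np.arange(n_cols) + 0.5) * cell_size
    yc = y0 - (np.arange(n_rows) + 0.5) * cell_size
    fcol = (xc - x0) / surface.cell_size - 0.5
    frow = (y0 - yc) / surface.cell_size - 0.5

    src = np.where(surface.mask, np.nan, surface.values)
    if categorical:
        rr = np.clip(np.round(frow).astype(int), 0, surface.n_rows - 1)
        cc = np.clip(np.round(fcol).astype(int), 0, surface.n_cols - 1)
        out = src[np.ix_(rr, cc)]
    else:
        from scipy.ndimage import map_coordinates

        grid_r, grid_c = np.meshgrid(
            np.clip(frow, 0, surface.n_rows - 1),
            np.clip(fcol, 0, surface.n_cols - 1),
            indexing="ij",
        )
        filled = np.where(np.isnan(src), np.nanmean(src), src)
        out = map_coordinates(filled, [grid_r, grid_c], order=1, mode="nearest")
        nn = map_coordinates(
            np.isnan(src).astype(float), [grid_r, grid_c], order=0, mode="nearest"
        )
        out = np.where(nn > 0, np.nan, out)
    return GridSurface(out, cell_size, surface.origin)
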
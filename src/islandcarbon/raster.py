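"""Single-band georeferenced grids.

The grid contract used throughout the package: projected coordinates in
meters, top-left origin at the *outer corner* of cell (0, 0), row-major
storage with row 0 at the top, cell-center registration for point lookups,
half-open cell intervals. Nodata is carried as NaN in memory and encoded as
a sentinel on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

__all__ = ["RasterGrid", "AlignmentError", "read_geotiff"]

# GeoTIFF tag codes (OGC GeoTIFF 1.1) + GDAL's nodata convention
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class AlignmentError(ValueError):
    """Two grids do not share origin, cell size and shape."""


@dataclass
class RasterGrid:
    """A 2-D georeferenced array with nodata.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values; NaN marks nodata.
    origin : (float, float)
        (x, y) of the outer top-left corner, map units (m).
    cell_size : float
        Cell edge length in meters; cells are square.
    nodata : float
        Sentinel written to disk in place of NaN.
    """

    values: np.ndarray
    origin: tuple[float, float]
    cell_size: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    # ------------------------------------------------------------------ geometry
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer edges."""
        nrows, ncols = self.shape
        x0, y0 = self.origin
        return (x0, y0 - nrows * self.cell_size, x0 + ncols * self.cell_size, y0)

    def cell_center(self, row, col):
        """Map coordinates of cell centers (vectorized)."""
        x0, y0 = self.origin
        x = x0 + (np.asarray(col) + 0.5) * self.cell_size
        y = y0 - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def index_of(self, x, y):
        """(row, col) of the cells containing map points; half-open intervals."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        row = np.floor((y0 - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y):
        xmin, ymin, xmax, ymax = self.bounds
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)

    def cell_centers(self):
        """Meshgrid arrays (X, Y) of all cell centers."""
        nrows, ncols = self.shape
        cols = np.arange(ncols)
        rows = np.arange(nrows)
        x = self.origin[0] + (cols + 0.5) * self.cell_size
        y = self.origin[1] - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)

    # ------------------------------------------------------------------ predicates
    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    def aligned_with(self, other: "RasterGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def require_aligned(self, other: "RasterGrid", what: str = "raster") -> None:
        if not self.aligned_with(other):
            raise AlignmentError(
                f"misaligned {what}: origin/cell/shape "
                f"{self.origin}/{self.cell_size}/{self.shape} vs "
                f"{other.origin}/{other.cell_size}/{other.shape}"
            )

    # ------------------------------------------------------------------ derivation
    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return replace(self, values=np.asarray(values, dtype=float))

    def sample(self, x, y, order: int = 0):
        """Sample values at map points (order 0 = nearest, 1 = bilinear)."""
        from scipy.ndimage import map_coordinates

        x0, y0 = self.origin
        scalar = np.isscalar(x) and np.isscalar(y)
        c = (np.atleast_1d(np.asarray(x, dtype=float)) - x0) / self.cell_size - 0.5
        r = (y0 - np.atleast_1d(np.asarray(y, dtype=float))) / self.cell_size - 0.5
        out = map_coordinates(self.values, [r, c], order=order, mode="nearest")
        return float(out[0]) if scalar else out

    def block_aggregate(
        self, cell: float, min_valid_fraction: float = 0.5, how: str = "mean"
    ) -> "RasterGrid":
        """Aggregate to a coarser grid sharing this grid's origin.

        Fine cells are assigned to the coarse cell containing their center,
        so non-integer resolution ratios are handled. A coarse cell is
        nodata when the valid fraction of its fine cells falls below
        ``min_valid_fraction``.
        """
        if cell <= self.cell_size:
            raise ValueError("aggregation cell must exceed the fine cell size")
        nrows, ncols = self.shape
        X, Y = self.cell_centers()
        crow = np.floor((self.origin[1] - Y) / cell).astype(int)
        ccol = np.floor((X - self.origin[0]) / cell).astype(int)
        out_shape = (crow.max() + 1, ccol.max() + 1)
        flat = crow * out_shape[1] + ccol
        valid = self.valid_mask
        total = np.bincount(flat.ravel(), minlength=out_shape[0] * out_shape[1])
        nval = np.bincount(
            flat.ravel(), weights=valid.ravel().astype(float),
            minlength=out_shape[0] * out_shape[1],
        )
        vals = np.where(valid, self.values, 0.0)
        ssum = np.bincount(
            flat.ravel(), weights=vals.ravel(), minlength=out_shape[0] * out_shape[1]
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = ssum / nval
        frac = np.where(total > 0, nval / total, 0.0)
        mean[frac < min_valid_fraction] = np.nan
        if how != "mean":
            raise ValueError(f"unknown aggregation: {how!r}")
        return RasterGrid(
            mean.reshape(out_shape), origin=self.origin, cell_size=float(cell),
            nodata=self.nodata,
        )

    # ------------------------------------------------------------------ I/O
    def write_geotiff(self, path) -> None:
        """Write a single-band float64 GeoTIFF (pixel scale, tiepoint, nodata tags)."""
        out = np.where(np.isfinite(self.values), self.values, self.nodata)
        extratags = [
            (_TAG_PIXEL_SCALE, "d", 3, (self.cell_size, self.cell_size, 0.0)),
            (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, self.origin[0], self.origin[1], 0.0)),
            (_TAG_GDAL_NODATA, "s", 0, str(self.nodata)),
        ]
        tifffile.imwrite(str(path), out, extratags=extratags)


def align_raster(source: RasterGrid, template: RasterGrid,
                 method: str = "nearest") -> RasterGrid:
    """Explicitly regrid ``source`` onto ``template``'s lattice.

    The codecs never resample silently; this is the one place regridding
    happens, and only when asked. ``method`` is 'nearest' or 'bilinear'.
    Template cells outside the source extent are nodata.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError("method must be 'nearest' or 'bilinear'")
    X, Y = template.cell_centers()
    inside = source.contains(X, Y)
    vals = source.sample(X.ravel(), Y.ravel(),
                         order=0 if method == "nearest" else 1)
    out = vals.reshape(template.shape)
    out[~inside] = np.nan
    return RasterGrid(out, origin=template.origin, cell_size=template.cell_size,
                      nodata=source.nodata)


def read_geotiff(path) -> RasterGrid:
    """Read a single-band GeoTIFF written by :meth:`RasterGrid.write_geotiff`
    (or any GeoTIFF carrying pixel-scale + tiepoint tags)."""
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray().astype(float)
        tags = page.tags
        try:
            sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
            tie = tags[_TAG_TIEPOINT].value
        except KeyError as exc:
            raise ValueError(f"{path}: missing georeferencing tags") from exc
        if abs(sx - sy) > 1e-9:
            raise ValueError(f"{path}: non-square cells unsupported ({sx} x {sy})")
        origin = (float(tie[3]), float(tie[4]))
        nodata = -9999.0
        if _TAG_GDAL_NODATA in tags:
            nodata = float(str(tags[_TAG_GDAL_NODATA].value).strip("\x00 "))
    values[values == nodata] = np.nan
    return RasterGrid(values, origin=origin, cell_size=float(sx), nodata=nodata)
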
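"""Ground classification and canopy surface models.

The processing chain mirrors standard discrete-return LiDAR practice:
ground seeds are the lowest return in each 10 m x 10 m kernel; the ground
set is then grown by progressive densification — a local plane is fitted
through the nearest already-classified ground returns and any return less
than ``vertical_tolerance`` (1.5 m) above that plane is admitted, iterated
to a fixed point. The DTM interpolates classified ground returns; the DSM
interpolates all first returns at 1.12 m; their difference, clamped at
zero, is top-of-canopy height (TCH), which is block-averaged onto the
30 m accounting grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.spatial import cKDTree, QhullError

from .pointcloud import PointCloud
from .raster import RasterGrid

__all__ = [
    "GroundFilterParams",
    "DegenerateGeometryError",
    "classify_ground",
    "build_dtm",
    "build_dsm",
    "compute_tch",
    "aggregate_tch",
]


class DegenerateGeometryError(ValueError):
    """Point set is collinear/degenerate; no surface can be interpolated."""


@dataclass
class GroundFilterParams:
    """Ground filter and surface-model parameters (meters throughout)."""

    kernel_size: float = 10.0
    vertical_tolerance: float = 1.5
    dsm_resolution: float = 1.12
    tch_cell: float = 30.0
    #: 'fitted' = local least-squares plane; 'horizontal' = constant plane at
    #: the mean elevation of the neighbors (the literal reading of a
    #: horizontal plane through each seed).
    plane: str = "fitted"
    neighbors: int = 8
    max_iterations: int = 60

    def __post_init__(self) -> None:
        for name in ("kernel_size", "vertical_tolerance", "dsm_resolution", "tch_cell"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.plane not in ("fitted", "horizontal"):
            raise ValueError("plane must be 'fitted' or 'horizontal'")


def _seed_lowest_per_kernel(cloud: PointCloud, kernel: float) -> np.ndarray:
    """Indices of the lowest return in each kernel cell.

    Ties on elevation break by (x, then y) for determinism.
    """
    x0, y0 = cloud.x.min(), cloud.y.min()
    kx = np.floor((cloud.x - x0) / kernel).astype(np.int64)
    ky = np.floor((cloud.y - y0) / kernel).astype(np.int64)
    kid = kx * (ky.max() + 1) + ky
    order = np.lexsort((cloud.y, cloud.x, cloud.z))  # z primary, then x, then y
    kid_sorted = kid[order]
    _, first = np.unique(kid_sorted, return_index=True)
    return order[first]


def _batched_plane_z(nx, ny, nz, qx, qy, ridge: float = 1e-6) -> np.ndarray:
    """Least-squares plane through each point's neighbor set, evaluated at the point.

    nx, ny, nz: (n, k) neighbor coordinates; qx, qy: (n,) query points.
    Coordinates are centered on the query point, so the plane intercept is
    the sought elevation. A small ridge keeps near-degenerate neighborhoods
    solvable; those degrade toward the horizontal (mean) plane.
    """
    dx = nx - qx[:, None]
    dy = ny - qy[:, None]
    ones = np.ones_like(dx)
    A = np.stack([dx, dy, ones], axis=2)  # (n, k, 3)
    G = np.einsum("nki,nkj->nij", A, A)
    G += ridge * np.eye(3)
    b = np.einsum("nki,nk->ni", A, nz)
    coef = np.linalg.solve(G, b[..., None])[..., 0]
    return coef[:, 2]


def classify_ground(cloud: PointCloud, params: GroundFilterParams | None = None) -> np.ndarray:
    """Boolean mask of ground-classified returns.

    Raises
    ------
    ValueError
        If the cloud holds fewer than 3 points (no plane is defined).
    """
    params = params or GroundFilterParams()
    n = len(cloud)
    if n < 3:
        raise ValueError("ground classification requires at least 3 points")

    ground = np.zeros(n, dtype=bool)
    ground[_seed_lowest_per_kernel(cloud, params.kernel_size)] = True

    k = params.neighbors
    for _ in range(params.max_iterations):
        todo = np.flatnonzero(~ground)
        if todo.size == 0:
            break
        gidx = np.flatnonzero(ground)
        tree = cKDTree(np.column_stack([cloud.x[gidx], cloud.y[gidx]]))
        kk = min(k, gidx.size)
        _, nb = tree.query(np.column_stack([cloud.x[todo], cloud.y[todo]]), k=kk)
        if kk == 1:
            nb = nb[:, None]
        nidx = gidx[nb]
        nz = cloud.z[nidx]
        if params.plane == "horizontal" or kk < 3:
            plane_z = nz.mean(axis=1)
        else:
            plane_z = _batched_plane_z(cloud.x[nidx], cloud.y[nidx], nz,
                                       cloud.x[todo], cloud.y[todo])
        admit = (cloud.z[todo] - plane_z) < params.vertical_tolerance
        if not admit.any():
            break
        ground[todo[admit]] = True
    return ground


def _surface_from_points(x, y, z, resolution, bounds, cutoff) -> RasterGrid:
    if len(x) < 3:
        raise ValueError("surface interpolation requires at least 3 points")
    if bounds is None:
        bounds = (x.min(), y.min(), x.max(), y.max())
    xmin, ymin, xmax, ymax = bounds
    ncols = max(1, int(np.ceil((xmax - xmin) / resolution)))
    nrows = max(1, int(np.ceil((ymax - ymin) / resolution)))
    # anchor at the top-left corner so coarser aggregates share the lattice
    origin = (xmin, ymax)
    grid = RasterGrid(np.full((nrows, ncols), np.nan), origin=origin, cell_size=resolution)
    X, Y = grid.cell_centers()
    pts = np.column_stack([x, y])
    try:
        lin = LinearNDInterpolator(pts, z)
    except QhullError as exc:
        raise DegenerateGeometryError(f"degenerate point set: {exc}") from None
    vals = lin(X, Y)
    hole = ~np.isfinite(vals)
    if hole.any():
        near = NearestNDInterpolator(pts, z)
        vals[hole] = near(X[hole], Y[hole])
    if cutoff is not None:
        tree = cKDTree(pts)
        d, _ = tree.query(np.column_stack([X.ravel(), Y.ravel()]))
        vals[(d.reshape(vals.shape) > cutoff)] = np.nan
    grid.values[:] = vals
    return grid


def build_dtm(cloud: PointCloud, ground_mask: np.ndarray | None = None,
              resolution: float = 1.12, bounds=None, cutoff: float | None = 20.0) -> RasterGrid:
    """Interpolate classified ground returns into a terrain model.

    Linear interpolation on the Delaunay triangulation of the ground
    points, nearest-neighbor fill at the hull edges; cells farther than
    ``cutoff`` (default 2x the 10 m filter kernel) from any ground point
    are nodata.
    """
    g = cloud if ground_mask is None else cloud.subset(ground_mask)
    return _surface_from_points(g.x, g.y, g.z, resolution, bounds, cutoff)


def build_dsm(cloud: PointCloud, resolution: float = 1.12, bounds=None,
              cutoff: float | None = None) -> RasterGrid:
    """Interpolate all first returns into the top-most surface model.

    First returns are dense (sub-meter spacing at >= 4 pulses m^-2), so
    the default support cutoff is 2.5x the DSM resolution: the surface
    does not extrapolate beyond the flown footprint. (The DTM keeps a
    wide cutoff because classified ground returns are sparse under dense
    canopy.)
    """
    first = cloud.first_returns
    if len(first) == 0:
        raise ValueError("cloud has no first returns; cannot build a DSM")
    if cutoff is None:
        cutoff = 2.5 * resolution
    return _surface_from_points(first.x, first.y, first.z, resolution, bounds, cutoff)


def compute_tch(dsm: RasterGrid, dtm: RasterGrid) -> RasterGrid:
    """TCH = DSM - DTM, clamped at zero; nodata propagates."""
    dsm.require_aligned(dtm, "DSM/DTM pair")
    diff = dsm.values - dtm.values
    neg = diff < 0
    if neg.any():
        diff = np.where(neg, 0.0, diff)
    return dsm.copy_with(diff)


def aggregate_tch(tch_fine: RasterGrid, tch_cell: float = 30.0,
                  min_valid_fraction: float = 0.5) -> RasterGrid:
    """Mean TCH per coarse accounting cell (default 30 m).

    Coarse cells whose valid-fine-cell fraction is below
    ``min_valid_fraction`` become nodata.
    """
    ratio = tch_cell / tch_fine.cell_size
    if abs(ratio - round(ratio)) > 0.05 * ratio:
        warnings.warn(
            f"tch_cell ({tch_cell}) is not close to a multiple of the fine "
            f"resolution ({tch_fine.cell_size}); fine cells are assigned by "
            "center containment", stacklevel=2)
    return tch_fine.block_aggregate(tch_cell, min_valid_fraction=min_valid_fraction)
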
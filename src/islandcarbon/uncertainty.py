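"""ACD-conditional uncertainty: binned RMSE plus a polynomial.

Paired (predicted, reference) carbon densities over the LiDAR footprint
are partitioned into bins across the predicted range (default 30), the
RMSE of the prediction error is computed per bin, and a low-order
polynomial (default quadratic) of RMSE against bin center — weighted by
bin population — turns the per-bin estimates into a smooth per-cell
uncertainty rule. Applied to a map it yields an RMSE raster (clamped at
zero) and optionally a percent-uncertainty layer.
"""

from __future__ import annotations

import json

import numpy as np
from sklearn.base import BaseEstimator

from .raster import RasterGrid

__all__ = ["BinnedRmseModel", "apply_uncertainty"]


class BinnedRmseModel(BaseEstimator):
    """Fit RMSE(predicted ACD) by binning then polynomial smoothing.

    Parameters
    ----------
    n_bins : int
        Bins across the predicted range (default 30).
    degree : int
        Polynomial degree, 1-4 (default 2).
    min_bin_count : int
        Bins with fewer pairs are merged with their right neighbor.
    binning : 'width' or 'quantile'
        Equal-width bins on predicted ACD (default) or equal-count bins.
    """

    def __init__(self, n_bins: int = 30, degree: int = 2,
                 min_bin_count: int = 5, binning: str = "width"):
        self.n_bins = n_bins
        self.degree = degree
        self.min_bin_count = min_bin_count
        self.binning = binning

    def fit(self, predicted, reference):
        if not 1 <= self.degree <= 4:
            raise ValueError("degree must be between 1 and 4")
        if self.binning not in ("width", "quantile"):
            raise ValueError("binning must be 'width' or 'quantile'")
        p = np.asarray(predicted, dtype=float).ravel()
        r = np.asarray(reference, dtype=float).ravel()
        if p.shape != r.shape:
            raise ValueError("predicted and reference must pair up")
        ok = np.isfinite(p) & np.isfinite(r)
        p, r = p[ok], r[ok]
        need = self.n_bins * self.min_bin_count
        if len(p) < need:
            raise ValueError(
                f"{len(p)} valid pairs; the uncertainty model needs at least "
                f"{need} (n_bins * {self.min_bin_count})")
        if self.binning == "width":
            edges = np.linspace(p.min(), p.max(), self.n_bins + 1)
        else:
            edges = np.unique(np.quantile(p, np.linspace(0, 1, self.n_bins + 1)))
        # merge under-populated bins into their right neighbor (left at the end)
        sq = (p - r) ** 2
        idx = np.clip(np.searchsorted(edges, p, side="right") - 1, 0, len(edges) - 2)
        keep_edges = list(edges)
        while True:
            counts = np.bincount(idx, minlength=len(keep_edges) - 1)
            small = np.flatnonzero(counts < self.min_bin_count)
            if small.size == 0 or len(keep_edges) <= 2:
                break
            b = int(small[0])
            drop = b + 1 if b + 1 < len(keep_edges) - 1 else b
            keep_edges.pop(drop)
            idx = np.clip(np.searchsorted(keep_edges, p, side="right") - 1,
                          0, len(keep_edges) - 2)
        nb = len(keep_edges) - 1
        counts = np.bincount(idx, minlength=nb)
        mean_sq = np.bincount(idx, weights=sq, minlength=nb) / np.maximum(counts, 1)
        centers = np.bincount(idx, weights=p, minlength=nb) / np.maximum(counts, 1)
        rmse = np.sqrt(mean_sq)
        use = counts > 0
        self.coeffs_ = np.polyfit(centers[use], rmse[use], self.degree,
                                  w=np.sqrt(counts[use]))
        self.bin_edges_ = np.asarray(keep_edges)
        self.bin_rmse_ = rmse
        self.bin_counts_ = counts
        self.bin_centers_ = centers
        self.n_pairs_ = len(p)
        return self

    def predict(self, acd):
        """Polynomial RMSE at the given ACD values, clamped at >= 0."""
        arr = np.asarray(acd, dtype=float)
        out = np.full(arr.shape, np.nan)
        ok = np.isfinite(arr)
        out[ok] = np.maximum(np.polyval(self.coeffs_, arr[ok]), 0.0)
        if np.isscalar(acd) or arr.ndim == 0:
            return float(out)
        return out

    # persistence -----------------------------------------------------------
    def to_json(self, path=None) -> str:
        payload = json.dumps({
            "format_version": 1,
            "degree": self.degree,
            "n_bins": self.n_bins,
            "binning": self.binning,
            "bin_edges": self.bin_edges_.tolist(),
            "bin_rmse": self.bin_rmse_.tolist(),
            "bin_counts": self.bin_counts_.tolist(),
            "coeffs": self.coeffs_.tolist(),
            "n_pairs": int(self.n_pairs_),
        }, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, source) -> "BinnedRmseModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            d = json.loads(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        model = cls(n_bins=d["n_bins"], degree=d["degree"], binning=d["binning"])
        model.coeffs_ = np.asarray(d["coeffs"])
        model.bin_edges_ = np.asarray(d["bin_edges"])
        model.bin_rmse_ = np.asarray(d["bin_rmse"])
        model.bin_counts_ = np.asarray(d["bin_counts"])
        model.bin_centers_ = model.bin_edges_[:-1]
        model.n_pairs_ = d["n_pairs"]
        return model


def apply_uncertainty(model: BinnedRmseModel, acd_map: RasterGrid,
                      percent: bool = False):
    """Per-cell RMSE raster (and optionally RMSE/ACD where ACD > 0)."""
    rmse = acd_map.copy_with(model.predict(acd_map.values))
    if not percent:
        return rmse
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(acd_map.values > 0, rmse.values / acd_map.values * 100.0, np.nan)
    return rmse, acd_map.copy_with(pct)
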
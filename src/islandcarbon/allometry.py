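"""Carbon allometry: the TCH->ACD power law and the tree-level cascade.

Two routes to aboveground carbon density (ACD, Mg C ha^-1) live here:

* the plot-aggregate power law ``ACD = a * TCH^b`` (defaults a = 3.744,
  b = 1.391) applied to canopy-height rasters, and its calibration from
  paired (TCH, plot ACD) data;
* the inventory cascade that estimates each tree's aboveground biomass
  (AGB, kg) from species-specific models where available and otherwise
  from a pantropical general model ``AGB = c * (rho * D^2 * H)^p`` with
  wood density falling back species -> genus mean -> 0.5, and height
  imputed from species height models or the general ln-quadratic
  diameter-height model with environmental-stress parameter E.

Cluster-plot totals are expanded to per-hectare values by nested size
class (microplot / subplot / macroplot radii 2.07 / 7.32 / 17.95 m, four
subplots per cluster) and converted to carbon with a fixed fraction
(default 0.48).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, RegressorMixin

from .raster import RasterGrid

__all__ = [
    "DEFAULT_A", "DEFAULT_B", "tch_to_acd", "PowerLawACD", "fit_tch_acd",
    "PowerLawCalibration", "AllometryTable", "PlotGeometry", "estimate_tree_agb",
    "impute_height", "plot_acd", "default_allometry_table",
]

DEFAULT_A = 3.744
DEFAULT_B = 1.391

#: dbh threshold (cm) separating microplot stems from subplot/macroplot stems
LARGE_TREE_DBH = 12.7


# --------------------------------------------------------------------------- power law
def tch_to_acd(tch, a: float = DEFAULT_A, b: float = DEFAULT_B):
    """Apply the plot-aggregate power law elementwise.

    Accepts scalars, arrays or :class:`RasterGrid`; nodata propagates.
    Negative TCH is rejected.
    """
    if isinstance(tch, RasterGrid):
        return tch.copy_with(tch_to_acd(tch.values, a, b))
    arr = np.asarray(tch, dtype=float)
    finite = np.isfinite(arr)
    if np.any(arr[finite] < 0):
        raise ValueError("TCH must be non-negative")
    out = np.full_like(arr, np.nan)
    out[finite] = a * np.power(arr[finite], b)
    if np.isscalar(tch) or arr.ndim == 0:
        return float(out)
    return out


@dataclass
class PowerLawCalibration:
    a: float
    b: float
    r2: float
    rmse: float
    n: int
    a_loglog: float
    b_loglog: float

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError("power-law parameters must be positive")


def fit_tch_acd(tch, acd) -> PowerLawCalibration:
    """Nonlinear least squares for ACD = a * TCH^b.

    Log-log OLS provides the initial values (and is reported alongside);
    R^2 and RMSE are computed on the original Mg C ha^-1 scale.
    """
    tch = np.asarray(tch, dtype=float)
    acd = np.asarray(acd, dtype=float)
    if tch.shape != acd.shape:
        raise ValueError("TCH and ACD must pair up")
    if len(tch) < 10:
        raise ValueError("calibration requires at least 10 plots")
    if np.any(~np.isfinite(tch)) or np.any(~np.isfinite(acd)):
        raise ValueError("calibration pairs must be finite")
    if np.any(tch <= 0) or np.any(acd <= 0):
        raise ValueError("calibration pairs must be strictly positive "
                         "(zero/negative TCH or ACD present)")
    slope, intercept = np.polyfit(np.log(tch), np.log(acd), 1)
    a0, b0 = float(np.exp(intercept)), float(slope)
    popt, _ = curve_fit(lambda t, a, b: a * np.power(t, b), tch, acd,
                        p0=(a0, b0), maxfev=20000)
    a, b = float(popt[0]), float(popt[1])
    pred = a * np.power(tch, b)
    resid = acd - pred
    sst = np.sum((acd - acd.mean()) ** 2)
    r2 = 1.0 - float(np.sum(resid**2) / sst) if sst > 0 else 1.0
    rmse = float(np.sqrt(np.mean(resid**2)))
    return PowerLawCalibration(a, b, r2, rmse, len(tch), a0, b0)


class PowerLawACD(RegressorMixin, BaseEstimator):
    """sklearn-style wrapper around the TCH->ACD power law.

    Unfitted, ``predict`` applies the constructor parameters (the
    regional defaults); after ``fit`` it applies the calibrated ones.
    """

    def __init__(self, a: float = DEFAULT_A, b: float = DEFAULT_B):
        self.a = a
        self.b = b

    def fit(self, X, y):
        X = np.asarray(X, dtype=float).reshape(-1)
        cal = fit_tch_acd(X, np.asarray(y, dtype=float))
        self.a_ = cal.a
        self.b_ = cal.b
        self.calibration_ = cal
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float).reshape(-1)
        a = getattr(self, "a_", self.a)
        b = getattr(self, "b_", self.b)
        return tch_to_acd(X, a, b)


# --------------------------------------------------------------------------- tables
@dataclass
class SpeciesAGBModel:
    """AGB (kg) = c0 * dbh^c1, valid for dbh in [dbh_min, dbh_max] cm."""

    c0: float
    c1: float
    dbh_min: float
    dbh_max: float

    def __call__(self, dbh: float) -> float:
        return self.c0 * dbh**self.c1

    def in_range(self, dbh: float) -> bool:
        return self.dbh_min <= dbh <= self.dbh_max


@dataclass
class AllometryTable:
    """Editable model/lookup bundle backing the cascade."""

    agb_models: dict[str, SpeciesAGBModel] = field(default_factory=dict)
    height_models: dict[str, tuple[float, float]] = field(default_factory=dict)  # H = c0*dbh^c1
    wood_density_species: dict[str, float] = field(default_factory=dict)
    wood_density_genus: dict[str, float] = field(default_factory=dict)
    default_density: float = 0.5
    #: general AGB model AGB = general_c * (rho * dbh^2 * H)^general_p
    general_c: float = 0.0673
    general_p: float = 0.976
    #: general height model ln H = h0 - E + h1 ln D + h2 (ln D)^2
    height_h0: float = 0.893
    height_h1: float = 0.760
    height_h2: float = -0.0340
    stress_E: float = 0.1

    def wood_density(self, species: str) -> tuple[float, str]:
        """(density, provenance) with species -> genus -> default fallback."""
        if species in self.wood_density_species:
            return self.wood_density_species[species], "species-rho"
        genus = species.split()[0] if species else ""
        if genus in self.wood_density_genus:
            return self.wood_density_genus[genus], "genus-rho"
        return self.default_density, "default-rho"


def default_allometry_table() -> AllometryTable:
    """Load the bundled (synthetic placeholder) model tables."""
    data = importlib.resources.files("islandcarbon") / "data"
    table = AllometryTable()
    agb = pd.read_csv(str(data / "species_agb_models_synthetic.csv"))
    for _, r in agb.iterrows():
        table.agb_models[r["species"]] = SpeciesAGBModel(
            float(r["c0"]), float(r["c1"]), float(r["dbh_min"]), float(r["dbh_max"]))
    hgt = pd.read_csv(str(data / "species_height_models_synthetic.csv"))
    for _, r in hgt.iterrows():
        table.height_models[r["species"]] = (float(r["c0"]), float(r["c1"]))
    wd = pd.read_csv(str(data / "wood_density_synthetic.csv"))
    for _, r in wd.iterrows():
        if r["level"] == "species":
            table.wood_density_species[r["name"]] = float(r["density"])
        else:
            table.wood_density_genus[r["name"]] = float(r["density"])
    return table


# --------------------------------------------------------------------------- cascade
def impute_height(dbh: float, species: str, table: AllometryTable,
                  E: float | None = None) -> float:
    """Tree height (m) from a species model, else the general E-model."""
    if dbh <= 0:
        raise ValueError("dbh must be positive")
    if species in table.height_models:
        c0, c1 = table.height_models[species]
        return float(c0 * dbh**c1)
    E = table.stress_E if E is None else E
    ln_d = np.log(dbh)
    return float(np.exp(table.height_h0 - E + table.height_h1 * ln_d
                        + table.height_h2 * ln_d**2))


def estimate_tree_agb(tree, table: AllometryTable) -> tuple[float, str]:
    """AGB (kg) of one stem plus a provenance code.

    ``tree`` is any mapping/namespace with ``species``, ``dbh`` (cm) and
    optionally ``height`` (m; imputed when missing). Provenance is one of
    ``species-model``, ``general+species-rho``, ``general+genus-rho``,
    ``general+default-rho``.
    """
    get = tree.get if hasattr(tree, "get") else lambda k, d=None: getattr(tree, k, d)
    species = get("species") or ""
    dbh = get("dbh")
    if dbh is None or not np.isfinite(dbh) or dbh <= 0:
        raise ValueError(f"tree of species {species!r}: dbh must be positive")
    model = table.agb_models.get(species)
    if model is not None and model.in_range(dbh):
        return float(model(dbh)), "species-model"
    height = get("height")
    if height is None or not np.isfinite(height) or height <= 0:
        height = impute_height(dbh, species, table)
    rho, rho_src = table.wood_density(species)
    agb = table.general_c * (rho * dbh**2 * height) ** table.general_p
    return float(agb), f"general+{rho_src}"


@dataclass
class PlotGeometry:
    """FIA-style cluster geometry: four circular subplots with nested plots."""

    n_subplots: int = 4
    radius_microplot: float = 2.07
    radius_subplot: float = 7.32
    radius_macroplot: float = 17.95
    protocol: str = "EXPFOR"

    def class_area_m2(self, subplot_class: str) -> float:
        r = {"microplot": self.radius_microplot,
             "subplot": self.radius_subplot,
             "macroplot": self.radius_macroplot}[subplot_class]
        return self.n_subplots * np.pi * r**2


def plot_acd(trees: pd.DataFrame, table: AllometryTable,
             geometry: PlotGeometry | None = None,
             carbon_fraction: float = 0.48,
             return_details: bool = False):
    """Cluster-plot ACD (Mg C ha^-1) from tree records.

    Each size class expands by its own cluster area (4 * pi * r^2); class
    per-hectare AGB values are summed and multiplied by the carbon
    fraction. Trees recorded in a size class inconsistent with their dbh
    (microplot stems must be < 12.7 cm, subplot/macroplot stems >= 12.7)
    raise a validation error listing the offenders.
    """
    geometry = geometry or PlotGeometry()
    if len(trees) == 0:
        return (0.0, pd.DataFrame()) if return_details else 0.0
    required = {"species", "dbh", "subplot_class"}
    missing = required - set(trees.columns)
    if missing:
        raise ValueError(f"inventory table missing columns: {sorted(missing)}")
    small = trees["dbh"] < LARGE_TREE_DBH
    micro = trees["subplot_class"] == "microplot"
    bad = trees.index[(micro & ~small) | (~micro & small)]
    if len(bad):
        raise ValueError(
            "trees recorded in the wrong size class for their dbh: "
            + ", ".join(f"row {i} (dbh={trees.loc[i, 'dbh']}, "
                        f"class={trees.loc[i, 'subplot_class']})" for i in bad))
    agb = np.empty(len(trees))
    prov = []
    for j, (_, row) in enumerate(trees.iterrows()):
        agb[j], p = estimate_tree_agb(row, table)
        prov.append(p)
    acd = 0.0
    for cls, grp_idx in trees.groupby("subplot_class").groups.items():
        area = geometry.class_area_m2(str(cls))
        agb_per_m2 = agb[trees.index.get_indexer(grp_idx)].sum() / area
        acd += agb_per_m2 * 10.0  # kg m^-2 -> Mg ha^-1
    acd *= carbon_fraction
    if return_details:
        det = trees.copy()
        det["agb_kg"] = agb
        det["provenance"] = prov
        return float(acd), det
    return float(acd)
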
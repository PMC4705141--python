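"""Self-consistent synthetic island scenes with known ground truth.

A scene couples a smooth terrain field, a 30 m predictor stack, a canopy
height field constructed as a *known* function of the predictors (plus
optional noise), a discrete-return LiDAR acquisition over a footprint at
>= 4 pulses m^-2, and FIA-style cluster-plot inventories whose stem lists
are filled until the plot honors the TCH->ACD power law on average. Every
downstream stage of the pipeline can therefore be checked against truth
without any external data.

Canopy height is block-constant within each 30 m cell (it is defined at
the predictor resolution), which makes block-averaged truth an exact
oracle for the aggregated TCH map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import allometry
from .pointcloud import PointCloud
from .raster import RasterGrid
from .stack import PREDICTOR_NAMES, PredictorStack

__all__ = [
    "SceneTruth", "SimulatedAcquisition", "PlotInventory",
    "generate_terrain", "generate_canopy", "generate_predictor_stack",
    "simulate_point_cloud", "generate_inventory", "generate_scene",
    "default_effects", "write_scene", "write_inventory_csv", "read_inventory_csv",
    "VEG_CLASSES", "TENURE_LABELS",
]

#: categorical vegetation classes used by the generator (1-based ids)
VEG_CLASSES = {
    1: "native_wet_forest",
    2: "native_mesic_forest",
    3: "alien_wet_forest",
    4: "alien_mesic_forest",
    5: "shrubland",
    6: "grassland",
}
NATIVE_CLASSES = (1, 2)
ALIEN_CLASSES = (3, 4)
FOREST_CLASSES = (1, 2, 3, 4)

TENURE_LABELS = {0: "unprotected", 1: "state", 2: "federal", 3: "private"}

#: FIA cluster layout: subplot 1 at the center, 2-4 at 36.58 m, azimuths 0/120/240
_SUBPLOT_AZIMUTHS_DEG = (None, 0.0, 120.0, 240.0)
_SUBPLOT_DISTANCE = 36.58


@dataclass
class SceneTruth:
    """Everything the generator knows about a synthetic island."""

    terrain: RasterGrid
    seed: int
    canopy: RasterGrid | None = None
    canopy_coarse: RasterGrid | None = None
    #: gap-weighted mean canopy height FC * h per 30 m cell — the quantity a
    #: DSM-minus-DTM TCH map measures under fractional canopy cover, and the
    #: height scale the plot-aggregate power law is calibrated against
    canopy_mean_coarse: RasterGrid | None = None
    stack: PredictorStack | None = None
    predictor_effects: dict | None = None
    zones: RasterGrid | None = None
    tenure: RasterGrid | None = None
    coarse_cell: float = 30.0

    @property
    def bounds(self):
        return self.terrain.bounds


@dataclass
class SimulatedAcquisition:
    """LiDAR acquisition settings for the simulator."""

    spot_spacing: float = 0.5
    pulse_density_min: float = 4.0
    footprint: tuple[float, float, float, float] | None = None
    vertical_noise_sd: float = 0.07
    #: floor on the per-pulse ground-penetration probability (1 - FC below it),
    #: guaranteeing a recoverable DTM under any cover
    ground_floor: float = 0.05
    #: when True, every canopy pulse yields both a canopy first return and a
    #: ground last return (noise-free oracle acquisitions)
    full_coverage: bool = False


@dataclass
class PlotInventory:
    """One FIA-style cluster plot drawn from the scene."""

    plot_id: str
    center: tuple[float, float]
    trees: pd.DataFrame  # species, dbh, height, subplot_class, subplot
    true_acd: float
    protocol: str = "EXPFOR"


# --------------------------------------------------------------------------- fields
def _smooth_field(shape, corr_cells, rng) -> np.ndarray:
    """Standardized Gaussian-filtered white noise (unit variance)."""
    f = gaussian_filter(rng.standard_normal(shape), corr_cells, mode="reflect")
    sd = f.std()
    return (f - f.mean()) / sd if sd > 0 else np.zeros(shape)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def generate_terrain(extent=(360.0, 360.0), resolution: float = 2.0,
                     roughness: float = 40.0, seed: int = 0,
                     base_elevation: float = 300.0,
                     correlation_length: float = 80.0) -> SceneTruth:
    """Smooth correlated elevation: filtered noise plus a planar trend.

    ``roughness`` (m) scales both components; zero yields a constant
    plane at ``base_elevation``. Deterministic per seed.
    """
    ex, ey = float(extent[0]), float(extent[1])
    if ex <= 0 or ey <= 0 or resolution <= 0:
        raise ValueError("extent and resolution must be positive")
    if roughness < 0:
        raise ValueError("roughness must be non-negative")
    ncols = max(1, round(ex / resolution))
    nrows = max(1, round(ey / resolution))
    rng = np.random.default_rng(seed)
    z = _smooth_field((nrows, ncols), correlation_length / resolution, rng)
    jj, ii = np.meshgrid(np.arange(ncols), np.arange(nrows))
    ramp = (ii / max(nrows - 1, 1) - 0.5) + (jj / max(ncols - 1, 1) - 0.5)
    values = base_elevation + roughness * (0.7 * z + 0.3 * ramp)
    terrain = RasterGrid(values, origin=(0.0, nrows * resolution), cell_size=resolution)
    return SceneTruth(terrain=terrain, seed=seed)


def default_effects() -> dict:
    """Default canopy model: FC and MAP drive height, with per-class offsets."""
    return {
        "FC": 8.0,
        "MAP": 4.0,
        "veg_type": {1: 4.0, 2: 2.0, 3: 5.0, 4: 2.5, 5: -5.0, 6: -7.0},
    }


def generate_canopy(scene: SceneTruth, predictor_effects: dict | None = None,
                    seed: int = 0, noise_sd: float = 1.5, intercept: float = 10.0,
                    coarse_cell: float = 30.0, bare_cutoff: float = 0.55,
                    n_veg_classes: int = 6) -> SceneTruth:
    """Build the 30 m predictor layers and a canopy field driven by them.

    ``predictor_effects`` maps layer names to coefficients applied to the
    standardized layer (the ``veg_type`` entry is a class->offset dict).
    With ``noise_sd = 0`` the canopy is an exact function of the stack.
    Canopy is clipped to [0, 60] m and zeroed where bare cover exceeds
    ``bare_cutoff`` (bare patches always exist in the default climate).
    """
    effects = default_effects() if predictor_effects is None else dict(predictor_effects)
    unknown = [k for k in effects if k not in PREDICTOR_NAMES]
    if unknown:
        raise ValueError(f"effects reference undefined predictor layers: {unknown}")
    rng = np.random.default_rng(seed)
    scene.coarse_cell = float(coarse_cell)

    elev = scene.terrain.block_aggregate(coarse_cell, min_valid_fraction=0.0)
    shape = elev.shape
    gy, gx = np.gradient(elev.values, coarse_cell)
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))
    aspect = np.where(slope > 0, (np.degrees(np.arctan2(gx, -gy)) + 360.0) % 360.0, 0.0)

    u = [_smooth_field(shape, 3.0, rng) for _ in range(12)]
    z_elev = _zscore(elev.values)
    MAP = np.clip(2200.0 + 800.0 * (0.7 * u[0] + 0.3 * z_elev), 200.0, None)
    z_map = _zscore(MAP)
    wind = np.clip(6.0 + 2.0 * u[1], 0.0, None)
    vpd = np.clip(0.9 + 0.3 * (0.6 * u[2] - 0.4 * z_map), 0.05, None)
    solar = np.clip(5.5 + 0.8 * u[3], 0.5, None)
    rh = np.clip(75.0 + 10.0 * (0.5 * u[4] + 0.5 * z_map), 5.0, 100.0)
    cloud = np.clip(0.45 + 0.2 * (0.6 * u[5] + 0.4 * z_map), 0.0, 1.0)
    lfs = 1.0 / (1.0 + np.exp(-u[6]))
    mfs = 1.0 / (1.0 + np.exp(-u[7]))
    rfs = 1.0 / (1.0 + np.exp(-(0.7 * u[8] - 0.5 * z_map)))
    mfri = np.exp(4.0 + 0.8 * u[9])

    # fractional covers on the simplex via softmax of smooth logits
    l_fc = 0.5 + 0.8 * z_map + 0.8 * u[10]
    l_npv = 0.4 * u[1] + 0.2 * u[4]
    l_bare = -0.3 + 0.8 * u[11] - 0.6 * z_map
    logits = np.stack([l_fc, l_npv, l_bare])
    logits -= logits.max(axis=0, keepdims=True)
    expv = np.exp(logits)
    expv /= expv.sum(axis=0, keepdims=True)
    fc, npv, bare = expv

    v_lat = 0.55 * z_map + 0.45 * u[3]
    qs = np.quantile(v_lat, np.linspace(0, 1, n_veg_classes + 1)[1:-1])
    veg = (np.searchsorted(qs, v_lat.ravel()).reshape(shape) + 1).astype(float)

    def grid(vals):
        return RasterGrid(vals, origin=elev.origin, cell_size=coarse_cell)

    layer_values = {
        "FC": fc, "NPV": npv, "bare": bare, "veg_type": veg,
        "elevation": elev.values, "slope": slope, "aspect": aspect,
        "MAP": MAP, "wind": wind, "VPD": vpd, "solar": solar, "RH": rh,
        "cloud": cloud, "LFS": lfs, "MFS": mfs, "RFS": rfs, "MFRI": mfri,
    }
    stack = PredictorStack({n: grid(layer_values[n]) for n in PREDICTOR_NAMES})

    canopy = np.full(shape, float(intercept))
    for name, eff in effects.items():
        if name == "veg_type":
            offsets = np.zeros(shape)
            for cls, off in eff.items():
                offsets[veg == cls] = off
            canopy += offsets
        else:
            canopy += eff * _zscore(layer_values[name])
    if noise_sd > 0:
        canopy += noise_sd * rng.standard_normal(shape)
    canopy[bare > bare_cutoff] = 0.0
    canopy = np.clip(canopy, 0.0, 60.0)

    canopy_coarse = grid(canopy)
    canopy_mean_coarse = grid(canopy * fc)
    # fine canopy is block-constant: each fine cell takes its coarse cell's value
    Xf, Yf = scene.terrain.cell_centers()
    rr, cc = canopy_coarse.index_of(Xf, Yf)
    rr = np.clip(rr, 0, shape[0] - 1)
    cc = np.clip(cc, 0, shape[1] - 1)
    canopy_fine = scene.terrain.copy_with(canopy[rr, cc])

    # districts: a 3 x 3 block partition of the coarse grid; tenure from a latent
    zr = (np.arange(shape[0]) * 3 // shape[0])[:, None]
    zc = (np.arange(shape[1]) * 3 // shape[1])[None, :]
    zones = grid((zr * 3 + zc + 1).astype(float) * np.ones(shape))
    t_lat = u[5] + 0.3 * u[9]
    tq = np.quantile(t_lat, [0.35, 0.45, 0.53])
    tenure_v = np.zeros(shape)
    tenure_v[t_lat <= tq[0]] = 1
    tenure_v[(t_lat > tq[0]) & (t_lat <= tq[1])] = 2
    tenure_v[(t_lat > tq[1]) & (t_lat <= tq[2])] = 3
    tenure = grid(tenure_v)

    scene.canopy = canopy_fine
    scene.canopy_coarse = canopy_coarse
    scene.canopy_mean_coarse = canopy_mean_coarse
    scene.stack = stack
    scene.predictor_effects = effects
    scene.zones = zones
    scene.tenure = tenure
    return scene


def generate_predictor_stack(scene: SceneTruth, seed: int | None = None) -> PredictorStack:
    """Return the scene's 17-layer stack (built by :func:`generate_canopy`)."""
    if scene.stack is None:
        raise ValueError("scene is incomplete: generate_canopy must run first")
    scene.stack.require_canonical()
    return scene.stack


def generate_scene(extent=(360.0, 360.0), resolution: float = 2.0, seed: int = 0,
                   roughness: float = 40.0, noise_sd: float = 1.5,
                   predictor_effects: dict | None = None,
                   intercept: float = 10.0, coarse_cell: float = 30.0,
                   **canopy_kwargs) -> SceneTruth:
    """Terrain + canopy + stack in one call, with per-stage seeds derived
    from ``seed``. Extra keyword arguments pass to :func:`generate_canopy`."""
    s = np.random.SeedSequence(seed).generate_state(2) & 0x7FFFFFFF
    scene = generate_terrain(extent, resolution, roughness=roughness, seed=int(s[0]))
    scene.seed = seed
    return generate_canopy(scene, predictor_effects, seed=int(s[1]),
                           noise_sd=noise_sd, intercept=intercept,
                           coarse_cell=coarse_cell, **canopy_kwargs)


# --------------------------------------------------------------------------- lidar
def simulate_point_cloud(scene: SceneTruth,
                         acquisition: SimulatedAcquisition | None = None,
                         seed: int = 0) -> PointCloud:
    """Discrete first/last returns over the footprint at >= 4 pulses m^-2.

    Pulses sit on a jittered grid at the spot spacing. Where canopy is
    present a pulse intercepts it with probability equal to local
    fractional cover (FC); intercepted pulses additionally reach the
    ground with probability max(1 - FC, ground_floor), producing a last
    return at the terrain. Everything else is a single ground return.
    """
    if scene.canopy is None or scene.stack is None:
        raise ValueError("scene is incomplete: generate_canopy must run first")
    acq = acquisition or SimulatedAcquisition()
    xmin, ymin, xmax, ymax = scene.bounds
    fp = acq.footprint or (xmin, ymin, xmax, ymax)
    if not (xmin <= fp[0] < fp[2] <= xmax and ymin <= fp[1] < fp[3] <= ymax):
        raise ValueError(f"footprint {fp} empty or outside scene bounds {scene.bounds}")
    s = acq.spot_spacing
    nx = int((fp[2] - fp[0]) / s)
    ny = int((fp[3] - fp[1]) / s)
    if nx * ny == 0:
        raise ValueError("footprint too small for a single pulse")
    rng = np.random.default_rng(seed)
    jx, jy = rng.random((2, ny * nx))
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny))
    px = fp[0] + (gx.ravel() + jx) * s
    py = fp[1] + (gy.ravel() + jy) * s

    terr = scene.terrain.sample(px, py, order=1)
    h = scene.canopy.sample(px, py, order=0)
    fc = scene.stack["FC"].sample(px, py, order=0)

    has_canopy = h > 0.05
    hit = has_canopy if acq.full_coverage else has_canopy & (rng.random(len(px)) < fc)
    p_ground = np.ones(len(px)) if acq.full_coverage else np.maximum(1.0 - fc, acq.ground_floor)
    penetrates = hit & (rng.random(len(px)) < p_ground)

    def noise(n):
        return (acq.vertical_noise_sd * rng.standard_normal(n)
                if acq.vertical_noise_sd > 0 else np.zeros(n))

    xs = [px[hit], px[~hit], px[penetrates]]
    ys = [py[hit], py[~hit], py[penetrates]]
    zs = [terr[hit] + h[hit] + noise(hit.sum()),
          terr[~hit] + noise((~hit).sum()),
          terr[penetrates] + noise(penetrates.sum())]
    rs = [np.ones(hit.sum(), dtype=int),
          np.ones((~hit).sum(), dtype=int),
          np.full(penetrates.sum(), 2, dtype=int)]
    truth = [np.zeros(hit.sum(), dtype=bool),
             np.ones((~hit).sum(), dtype=bool),
             np.ones(penetrates.sum(), dtype=bool)]
    cloud = PointCloud(np.concatenate(xs), np.concatenate(ys), np.concatenate(zs),
                       np.concatenate(rs), truth_ground=np.concatenate(truth))
    area = (fp[2] - fp[0]) * (fp[3] - fp[1])
    if len(cloud) / area < acq.pulse_density_min:
        raise RuntimeError(
            f"realized return density {len(cloud) / area:.2f} m^-2 below the "
            f"{acq.pulse_density_min} m^-2 floor; decrease spot_spacing")
    return cloud


# --------------------------------------------------------------------------- plots
_SPECIES_POOLS = {
    "native": (["Metrosideros polymorpha", "Acacia koa", "Cibotium glaucum"],
               [0.6, 0.3, 0.1]),
    "alien": (["Falcataria moluccana", "Psidium cattleianum", "Fraxinus uhdei",
               "Eucalyptus robusta"], [0.35, 0.35, 0.2, 0.1]),
    "open": (["Psidium cattleianum", "Sophora chrysophylla"], [0.7, 0.3]),
}


def _subplot_centers(center):
    cx, cy = center
    out = [(cx, cy)]
    for az in _SUBPLOT_AZIMUTHS_DEG[1:]:
        rad = np.radians(az)
        out.append((cx + _SUBPLOT_DISTANCE * np.sin(rad),
                    cy + _SUBPLOT_DISTANCE * np.cos(rad)))
    return out


def generate_inventory(scene: SceneTruth, n_plots: int, protocol: str = "EXPFOR",
                       seed: int = 0, plot_noise_sd: float = 0.10,
                       table: allometry.AllometryTable | None = None,
                       margin: float = 55.0) -> list[PlotInventory]:
    """Draw FIA-style cluster plots whose stems realize the power law.

    Each subplot accumulates large stems (diameters scaled to the local
    canopy height) until its per-hectare carbon share reaches the local
    power-law target perturbed by lognormal noise of sd ``plot_noise_sd``;
    a few microplot stems are added on top. Under the EXPFOR protocol
    large stems are recorded on macroplots, otherwise on subplots. The
    plot's reference ACD is then recomputed through the same allometric
    cascade used for real inventories.
    """
    if n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    if scene.canopy_coarse is None:
        raise ValueError("scene is incomplete: generate_canopy must run first")
    table = table or allometry.default_allometry_table()
    geometry = allometry.PlotGeometry(protocol=protocol)
    large_class = "macroplot" if protocol == "EXPFOR" else "subplot"
    large_r = (geometry.radius_macroplot if protocol == "EXPFOR"
               else geometry.radius_subplot)
    large_area = 4 * np.pi * large_r**2

    xmin, ymin, xmax, ymax = scene.bounds
    if xmax - xmin <= 2 * margin or ymax - ymin <= 2 * margin:
        raise ValueError("scene too small to host cluster plots with the FIA layout")
    rng = np.random.default_rng(seed)
    veg = scene.stack["veg_type"] if scene.stack is not None else None

    plots: list[PlotInventory] = []
    for p in range(n_plots):
        cx = rng.uniform(xmin + margin, xmax - margin)
        cy = rng.uniform(ymin + margin, ymax - margin)
        rows = []
        for si, (sx, sy) in enumerate(_subplot_centers((cx, cy)), start=1):
            H = float(scene.canopy_coarse.sample(sx, sy, order=0))
            # carbon quota follows the gap-weighted height the TCH map measures
            Hmean = float(scene.canopy_mean_coarse.sample(sx, sy, order=0))
            if H <= 0.5 or Hmean <= 0.25:
                continue
            cls = int(veg.sample(sx, sy, order=0)) if veg is not None else 1
            pool = ("native" if cls in NATIVE_CLASSES
                    else "alien" if cls in ALIEN_CLASSES else "open")
            species_names, probs = _SPECIES_POOLS[pool]
            quota = allometry.tch_to_acd(Hmean) * np.exp(rng.normal(0, plot_noise_sd)) / 4.0
            acc = 0.0
            for _ in range(250):
                if acc >= quota:
                    break
                dbh = allometry.LARGE_TREE_DBH + rng.gamma(2.0, 1.2 + 0.45 * H)
                sp = species_names[rng.choice(len(species_names), p=probs)]
                height = float(np.clip(H * rng.normal(1.0, 0.12), 2.0, 65.0))
                agb, _prov = allometry.estimate_tree_agb(
                    {"species": sp, "dbh": dbh, "height": height}, table)
                acc += agb / large_area * 10.0 * 0.48
                rows.append((sp, round(dbh, 1), round(height, 1), large_class, si))
            for _ in range(rng.poisson(0.8)):
                dbh = rng.uniform(2.0, 12.0)
                sp = species_names[rng.choice(len(species_names), p=probs)]
                height = round(allometry.impute_height(dbh, sp, table), 1)
                rows.append((sp, round(dbh, 1), height, "microplot", si))
        trees = pd.DataFrame(rows, columns=["species", "dbh", "height",
                                            "subplot_class", "subplot"])
        true_acd = allometry.plot_acd(trees, table, geometry) if len(trees) else 0.0
        plots.append(PlotInventory(f"plot{p + 1:03d}", (cx, cy), trees,
                                   true_acd, protocol))
    return plots


# --------------------------------------------------------------------------- I/O
def write_inventory_csv(plots: list[PlotInventory], trees_path, plots_path) -> None:
    """Two-file inventory dialect: tree records + plot metadata.

    Column dictionary: trees(plot_id, subplot, species, dbh [cm at 1.37 m],
    height [m], subplot_class in {microplot, subplot, macroplot}); plots(
    plot_id, x, y [projected m, cluster center], true_acd [Mg C ha^-1,
    generator reference], protocol).
    """
    rows = []
    for p in plots:
        if len(p.trees) == 0:
            continue
        t = p.trees.copy()
        t.insert(0, "plot_id", p.plot_id)
        rows.append(t)
    trees = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=["plot_id", "species", "dbh", "height",
                                        "subplot_class", "subplot"]))
    trees.to_csv(trees_path, index=False)
    meta = pd.DataFrame(
        [(p.plot_id, p.center[0], p.center[1], p.true_acd, p.protocol) for p in plots],
        columns=["plot_id", "x", "y", "true_acd", "protocol"])
    meta.to_csv(plots_path, index=False)


def read_inventory_csv(trees_path, plots_path) -> list[PlotInventory]:
    trees = pd.read_csv(trees_path)
    meta = pd.read_csv(plots_path)
    required = {"plot_id", "species", "dbh", "subplot_class"}
    missing = required - set(trees.columns)
    if missing:
        raise ValueError(f"{trees_path}: missing inventory columns {sorted(missing)}")
    out = []
    for _, m in meta.iterrows():
        t = trees[trees["plot_id"] == m["plot_id"]].drop(columns=["plot_id"])
        out.append(PlotInventory(str(m["plot_id"]), (float(m["x"]), float(m["y"])),
                                 t.reset_index(drop=True), float(m["true_acd"]),
                                 str(m.get("protocol", "EXPFOR"))))
    return out


def write_scene(scene: SceneTruth, out_dir) -> None:
    """Persist a scene: GeoTIFF per layer plus a JSON manifest."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scene.terrain.write_geotiff(out / "terrain.tif")
    if scene.canopy is not None:
        scene.canopy.write_geotiff(out / "canopy.tif")
        scene.canopy_coarse.write_geotiff(out / "canopy_30m.tif")
        for name, layer in scene.stack.layers.items():
            layer.write_geotiff(out / f"predictor_{name}.tif")
        scene.zones.write_geotiff(out / "zones.tif")
        scene.tenure.write_geotiff(out / "tenure.tif")
    manifest = {
        "seed": scene.seed,
        "coarse_cell": scene.coarse_cell,
        "predictor_effects": scene.predictor_effects,
        "bounds": scene.bounds,
        "canopy_mean": (float(np.nanmean(scene.canopy_coarse.values))
                        if scene.canopy_coarse is not None else None),
    }
    (out / "scene_manifest.json").write_text(json.dumps(manifest, indent=2))
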
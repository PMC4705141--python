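"""End-to-end orchestration: cloud -> TCH -> model -> ACD -> reports.

`run_pipeline` is the file-based driver behind the CLI `run` subcommand;
`run_demo` executes the same stage sequence in memory on a synthetic
scene (the packaged integration example) and returns every intermediate
product for inspection.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from . import allometry, lidar, rfml, synthetic, uncertainty, validation
from .config import PipelineConfig
from .pointcloud import PointCloud, read_point_cloud
from .raster import RasterGrid, read_geotiff
from .stack import PREDICTOR_NAMES, PredictorStack

__all__ = ["RunManifest", "run_pipeline", "run_demo", "save_forest", "load_forest",
           "PipelineError"]

log = logging.getLogger(__name__)

FOREST_FORMAT_VERSION = 1


class PipelineError(RuntimeError):
    def __init__(self, stage: str, completed: list[str], cause: Exception):
        super().__init__(f"stage {stage!r} failed after {completed or 'no stages'}: {cause}")
        self.stage = stage
        self.completed = completed


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: list[str] = field(default_factory=list)
    wall_clock_s: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)

    def write(self, path) -> None:
        tmp = Path(str(path) + ".tmp")
        tmp.write_text(json.dumps(self.__dict__, indent=2, default=str))
        tmp.replace(path)  # atomic on POSIX


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def save_forest(forest, feature_names, path) -> None:
    joblib.dump({"format_version": FOREST_FORMAT_VERSION,
                 "feature_names": feature_names, "forest": forest}, path)


def load_forest(path):
    d = joblib.load(path)
    if d.get("format_version") != FOREST_FORMAT_VERSION:
        raise ValueError(f"{path}: unsupported forest file version {d.get('format_version')}")
    return d["forest"], d["feature_names"]


def load_stack(stack_dir) -> PredictorStack:
    stack_dir = Path(stack_dir)
    layers = {}
    missing = []
    for name in PREDICTOR_NAMES:
        p = stack_dir / f"predictor_{name}.tif"
        if p.exists():
            layers[name] = read_geotiff(p)
        else:
            missing.append(name)
    if missing:
        raise FileNotFoundError(f"{stack_dir}: missing predictor layers {missing}")
    return PredictorStack(layers)


# --------------------------------------------------------------------------- stages
def tch_stage(cloud, ground_cfg) -> dict:
    params = lidar.GroundFilterParams(
        kernel_size=ground_cfg.kernel_size,
        vertical_tolerance=ground_cfg.vertical_tolerance,
        dsm_resolution=ground_cfg.dsm_resolution,
        tch_cell=ground_cfg.tch_cell, plane=ground_cfg.plane)
    ground = lidar.classify_ground(cloud, params)
    # snap the processing extent to the 30 m accounting lattice
    cell = params.tch_cell
    bx = cloud.bounds()
    bounds = (np.floor(bx[0] / cell) * cell, np.floor(bx[1] / cell) * cell,
              np.ceil(bx[2] / cell) * cell, np.ceil(bx[3] / cell) * cell)
    dtm = lidar.build_dtm(cloud, ground, resolution=params.dsm_resolution, bounds=bounds)
    dsm = lidar.build_dsm(cloud, resolution=params.dsm_resolution, bounds=bounds)
    tch_fine = lidar.compute_tch(dsm, dtm)
    tch30 = lidar.aggregate_tch(tch_fine, params.tch_cell,
                                min_valid_fraction=ground_cfg.min_valid_fraction)
    return {"ground_mask": ground, "dtm": dtm, "dsm": dsm,
            "tch_fine": tch_fine, "tch_30m": tch30}


def _align_tch_to_stack(tch30: RasterGrid, stack: PredictorStack) -> RasterGrid:
    """Place footprint TCH cells onto the stack grid (no resampling:
    cells must share the 30 m lattice)."""
    grid = stack.grid
    if tch30.aligned_with(grid):
        return tch30
    dx = (tch30.origin[0] - grid.origin[0]) / grid.cell_size
    dy = (grid.origin[1] - tch30.origin[1]) / grid.cell_size
    if abs(tch30.cell_size - grid.cell_size) > 1e-6 or \
       abs(dx - round(dx)) > 1e-3 or abs(dy - round(dy)) > 1e-3:
        from .raster import AlignmentError

        raise AlignmentError(
            f"TCH grid (origin {tch30.origin}, cell {tch30.cell_size}) is not on "
            f"the stack lattice (origin {grid.origin}, cell {grid.cell_size})")
    out = np.full(grid.shape, np.nan)
    r0, c0 = int(round(dy)), int(round(dx))
    nr, nc = tch30.shape
    rr = slice(max(r0, 0), min(r0 + nr, grid.shape[0]))
    cc = slice(max(c0, 0), min(c0 + nc, grid.shape[1]))
    out[rr, cc] = tch30.values[rr.start - r0:rr.stop - r0, cc.start - c0:cc.stop - c0]
    return grid.copy_with(out)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute tch -> train -> predict -> acd -> uncertainty -> validate -> report.

    Each stage's outputs are written before the next starts; a failure
    raises :class:`PipelineError` naming the stage and listing completed
    stages.
    """
    from importlib.metadata import version as pkg_version

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        ver = pkg_version("islandcarbon")
    except Exception:
        ver = "unknown"
    manifest = RunManifest(config=config.model_dump(), version=ver)
    state: dict = {}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise PipelineError(name, manifest.stages, exc) from exc
        manifest.stages.append(name)
        manifest.wall_clock_s[name] = round(time.perf_counter() - t0, 3)

    def s_tch():
        cloud = read_point_cloud(config.point_cloud)
        res = tch_stage(cloud, config.ground)
        for key in ("dtm", "dsm", "tch_fine", "tch_30m"):
            res[key].write_geotiff(out / f"{key}.tif")
        state.update(res)

    def s_train():
        state["stack"] = load_stack(config.stack_dir)
        tch30 = _align_tch_to_stack(state["tch_30m"], state["stack"])
        table = rfml.assemble_training(tch30, state["stack"])
        forest = rfml.HoldoutForestRegressor(
            n_trees=config.forest.n_trees, holdout_size=config.forest.holdout_size,
            max_features=config.forest.max_features,
            min_samples_leaf=config.forest.min_samples_leaf,
            max_depth=config.forest.max_depth,
            random_state=config.seeds.train).fit(table.X, table.y)
        save_forest(forest, table.feature_names, out / "forest.joblib")
        imp = rfml.factor_importance(forest, table, seed=config.seeds.importance)
        imp.to_csv(out / "importance.csv", index=False)
        state.update(table=table, forest=forest)

    def s_predict():
        state["tch_pred"] = rfml.predict_tch(state["forest"], state["stack"],
                                             state["table"].feature_names)
        state["tch_pred"].write_geotiff(out / "tch_predicted.tif")

    def s_acd():
        a, b = config.calibration.a, config.calibration.b
        state["acd_map"] = allometry.tch_to_acd(state["tch_pred"], a, b)
        state["acd_lidar"] = allometry.tch_to_acd(
            _align_tch_to_stack(state["tch_30m"], state["stack"]), a, b)
        state["acd_map"].write_geotiff(out / "acd.tif")

    def s_uncertainty():
        model = uncertainty.BinnedRmseModel(
            n_bins=config.uncertainty.n_bins, degree=config.uncertainty.degree,
            binning=config.uncertainty.binning)
        both = state["acd_map"].valid_mask & state["acd_lidar"].valid_mask
        model.fit(state["acd_map"].values[both], state["acd_lidar"].values[both])
        model.to_json(out / "uncertainty_model.json")
        rmse = uncertainty.apply_uncertainty(model, state["acd_map"])
        rmse.write_geotiff(out / "acd_uncertainty.tif")
        state["uncertainty"] = model

    def s_validate():
        if not (config.inventory_trees and config.inventory_plots):
            log.info("no inventory provided; skipping validation")
            return
        plots = synthetic.read_inventory_csv(config.inventory_trees, config.inventory_plots)
        table = allometry.default_allometry_table()
        rows = []
        for p in plots:
            geometry = allometry.PlotGeometry(protocol=p.protocol)
            acd = allometry.plot_acd(p.trees, table, geometry,
                                     carbon_fraction=config.carbon_fraction)
            rows.append((p.plot_id, p.center[0], p.center[1], acd))
        pdf = pd.DataFrame(rows, columns=["plot_id", "x", "y", "plot_acd"])
        result = validation.validate_map(state["acd_map"], pdf)
        result.table.to_csv(out / "validation_pairs.csv", index=False)
        (out / "validation.json").write_text(json.dumps({
            "n_plots": result.n_plots, "r2": result.r2, "r2_sse": result.r2_sse,
            "rmse": result.rmse, "bias": result.bias}, indent=2))
        state["validation"] = result

    def s_report():
        mcfg = config.mask
        if mcfg.rule == "veg_classes":
            mask = validation.forest_mask(state["stack"]["veg_type"],
                                          rule="veg_classes", classes=mcfg.classes)
        else:
            mask = validation.forest_mask(state["tch_pred"], rule="tch",
                                          tch_threshold=mcfg.tch_threshold)
        mask.write_geotiff(out / "forest_mask.tif")
        if config.zones:
            zones = read_geotiff(config.zones)
            validation.zonal_summary(state["acd_map"], zones, mask).to_csv(
                out / "zonal_summary.csv", index=False)
        if config.tenure:
            tenure = read_geotiff(config.tenure)
            validation.protection_summary(state["acd_map"], mask, tenure).to_csv(
                out / "protection_summary.csv", index=False)

    stage("tch", s_tch)
    stage("train", s_train)
    stage("predict", s_predict)
    stage("acd", s_acd)
    stage("uncertainty", s_uncertainty)
    stage("validate", s_validate)
    stage("report", s_report)

    for f in sorted(out.iterdir()):
        if f.is_file() and f.name != "run_manifest.json":
            manifest.checksums[f.name] = _sha256(f)
    manifest.write(out / "run_manifest.json")
    return manifest


# --------------------------------------------------------------------------- demo
def run_demo(seed: int = 0, extent: tuple[float, float] = (360.0, 360.0),
             footprint_fraction: float = 0.5, n_plots: int = 36,
             n_trees: int = 250, noise_sd: float = 1.5,
             scene_kwargs: dict | None = None) -> dict:
    """The full chain on one synthetic scene, in memory.

    The LiDAR acquisition covers ``footprint_fraction`` of the scene as
    two parallel north-south strips spread across it — sampling flight
    lines are laid out to intersect the island's environmental gradients
    rather than one contiguous corner, so the training sample spans the
    canopy conditions the model must extrapolate to. The model predicts
    wall-to-wall and validation plots span the whole island. Returns all
    intermediate products keyed by stage name.
    """
    import warnings as _warnings

    s = np.random.SeedSequence(seed).generate_state(4) & 0x7FFFFFFF
    scene = synthetic.generate_scene(extent=extent, seed=int(s[0]), noise_sd=noise_sd,
                                     **(scene_kwargs or {}))
    xmin, ymin, xmax, ymax = scene.bounds
    W = xmax - xmin
    half = footprint_fraction / 2.0
    strips = [(xmin, ymin, xmin + half * W, ymax),
              (xmin + 0.5 * W, ymin, xmin + (0.5 + half) * W, ymax)]
    parts = [synthetic.simulate_point_cloud(
        scene, synthetic.SimulatedAcquisition(footprint=fp), seed=int(s[1]) + i)
        for i, fp in enumerate(strips)]
    cloud = PointCloud(
        np.concatenate([p.x for p in parts]), np.concatenate([p.y for p in parts]),
        np.concatenate([p.z for p in parts]),
        np.concatenate([p.return_number for p in parts]),
        truth_ground=np.concatenate([p.truth_ground for p in parts]))

    from .config import GroundFilterConfig
    res = tch_stage(cloud, GroundFilterConfig())
    tch30 = _align_tch_to_stack(res["tch_30m"], scene.stack)

    table = rfml.assemble_training(tch30, scene.stack)
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)  # small-table holdout shrink
        forest = rfml.HoldoutForestRegressor(
            n_trees=n_trees, random_state=int(s[2])).fit(table.X, table.y)
    imp = rfml.factor_importance(forest, table, seed=int(s[3]))
    tch_pred = rfml.predict_tch(forest, scene.stack, table.feature_names)
    acd_map = allometry.tch_to_acd(tch_pred)
    acd_lidar = allometry.tch_to_acd(tch30)

    both = acd_map.valid_mask & acd_lidar.valid_mask
    unc = None
    pairs = int(both.sum())
    if pairs >= 30:
        unc = uncertainty.BinnedRmseModel(n_bins=min(30, pairs // 5)).fit(
            acd_map.values[both], acd_lidar.values[both])

    plots = synthetic.generate_inventory(scene, n_plots=n_plots, seed=int(s[1]) + 1)
    alltab = allometry.default_allometry_table()
    rows = [(p.plot_id, p.center[0], p.center[1],
             allometry.plot_acd(p.trees, alltab,
                                allometry.PlotGeometry(protocol=p.protocol)))
            for p in plots]
    pdf = pd.DataFrame(rows, columns=["plot_id", "x", "y", "plot_acd"])
    result = validation.validate_map(acd_map, pdf)

    mask = validation.forest_mask(scene.stack["veg_type"], rule="veg_classes",
                                  classes=list(synthetic.FOREST_CLASSES))
    zonal = validation.zonal_summary(acd_map, scene.zones, mask)
    protection = validation.protection_summary(acd_map, mask, scene.tenure,
                                               labels=dict(enumerate(
                                                   ["unprotected", "state",
                                                    "federal", "private"])))
    return {"scene": scene, "cloud": cloud, **res, "tch_30m_on_stack": tch30,
            "table": table, "forest": forest, "importance": imp,
            "tch_pred": tch_pred, "acd_map": acd_map, "acd_lidar": acd_lidar,
            "uncertainty": unc, "plots": plots, "plot_table": pdf,
            "validation": result, "mask": mask, "zonal": zonal,
            "protection": protection}
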
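"""Regression-tree ensemble scaling of LiDAR canopy height to full coverage.

The ensemble follows the sampled-to-wall-to-wall design: the response is
30 m TCH over the LiDAR footprint, the features are the 17 environmental
layers, and each tree reserves its own randomly drawn 250-row holdout
(disjoint from that tree's training rows) on which permutation importance
is later scored as the mean relative MSE increase
``mean_i[(MSE*_i - MSE_i) / MSE_i]``.

Feature encoding: the categorical vegetation layer is one-hot expanded
(and permuted jointly as one factor); circular aspect becomes a sin/cos
pair, also treated as a single factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted

from .raster import RasterGrid
from .stack import PredictorStack

__all__ = ["TrainingTable", "assemble_training", "HoldoutForestRegressor",
           "factor_importance", "predict_tch", "stack_features"]

HOLDOUT_SIZE = 250


@dataclass
class TrainingTable:
    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    #: factor name -> column indices permuted jointly for importance
    factor_groups: dict[str, list[int]]
    #: flat cell index (into the 30 m grid) of each row
    cell_index: np.ndarray
    grid_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.y)


def _encode_layers(stack: PredictorStack, valid: np.ndarray,
                   veg_classes: list[int] | None = None):
    """Feature matrix + names + factor groups for the valid cells."""
    cols, names = [], []
    groups: dict[str, list[int]] = {}
    for name, layer in stack.layers.items():
        v = layer.values[valid]
        if stack.roles.get(name) == "categorical":
            classes = (sorted(np.unique(v[np.isfinite(v)]).astype(int))
                       if veg_classes is None else veg_classes)
            idx = []
            for c in classes:
                idx.append(len(cols))
                cols.append((v == c).astype(float))
                names.append(f"{name}={c}")
            groups[name] = idx
        elif name == "aspect":
            rad = np.radians(v)
            groups[name] = [len(cols), len(cols) + 1]
            cols.extend([np.sin(rad), np.cos(rad)])
            names.extend([f"{name}_sin", f"{name}_cos"])
        else:
            groups[name] = [len(cols)]
            cols.append(v)
            names.append(name)
    return np.column_stack(cols), names, groups


def assemble_training(tch_30m: RasterGrid, stack: PredictorStack) -> TrainingTable:
    """One row per cell where TCH and all predictor layers are valid."""
    stack.grid.require_aligned(tch_30m, "TCH grid vs predictor stack")
    valid = tch_30m.valid_mask & stack.valid_mask
    if not valid.any():
        raise ValueError("no cells with valid TCH and a complete predictor stack")
    X, names, groups = _encode_layers(stack, valid)
    return TrainingTable(X, tch_30m.values[valid], names, groups,
                         np.flatnonzero(valid.ravel()), tch_30m.shape)


class HoldoutForestRegressor(RegressorMixin, BaseEstimator):
    """Ensemble of CART regression trees with per-tree holdout bookkeeping.

    Parameters
    ----------
    n_trees : int
        Ensemble size (default 250).
    holdout_size : int
        Rows left out of each tree's training data, reserved for
        permutation importance (default 250). When the training table has
        fewer rows than this, the holdout shrinks to ``n // 5`` with a
        warning.
    max_features : 'third' or int
        Features examined per split; 'third' = ceil(p / 3).
    min_samples_leaf, max_depth :
        Passed to the underlying trees.
    random_state : int or None
        Seeds tree construction, holdout draws and bootstraps.
    """

    def __init__(self, n_trees: int = 250, holdout_size: int = HOLDOUT_SIZE,
                 max_features="third", min_samples_leaf: int = 5,
                 max_depth: int | None = None, random_state: int | None = None):
        self.n_trees = n_trees
        self.holdout_size = holdout_size
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.max_depth = max_depth
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        h = self.holdout_size
        if n <= h:
            h = max(1, n // 5)
            warnings.warn(
                f"training table has {n} rows <= holdout size "
                f"{self.holdout_size}; shrinking per-tree holdout to {h}",
                stacklevel=2)
        mf = int(np.ceil(p / 3)) if self.max_features == "third" else int(self.max_features)
        ss = np.random.SeedSequence(self.random_state)
        self.trees_ = []
        self.holdout_sets_ = []
        all_idx = np.arange(n)
        for child in ss.spawn(self.n_trees):
            rng = np.random.default_rng(child)
            hold = rng.choice(n, size=h, replace=False)
            pool = np.setdiff1d(all_idx, hold, assume_unique=False)
            boot = rng.choice(pool, size=len(pool), replace=True)
            tree = DecisionTreeRegressor(
                max_features=mf, min_samples_leaf=self.min_samples_leaf,
                max_depth=self.max_depth,
                random_state=int(rng.integers(0, 2**31 - 1)))
            tree.fit(X[boot], y[boot])
            self.trees_.append(tree)
            self.holdout_sets_.append(np.sort(hold))
        self.n_features_in_ = p
        self.y_min_, self.y_max_ = float(y.min()), float(y.max())
        return self

    def predict(self, X):
        check_is_fitted(self, "trees_")
        X = np.asarray(X, dtype=float)
        out = np.zeros(len(X))
        for tree in self.trees_:
            out += tree.predict(X)
        return out / len(self.trees_)


def factor_importance(forest: HoldoutForestRegressor, table: TrainingTable,
                      seed: int | None = None) -> pd.DataFrame:
    """Permutation importance on each tree's private holdout.

    For factor f and tree i, the f-block of the holdout feature matrix is
    row-permuted (jointly across the factor's columns) and the relative
    MSE increase ``(MSE*_i - MSE_i) / MSE_i`` is averaged over trees. A
    tree with a perfect holdout fit (MSE_i = 0) contributes
    ``MSE*_i / var(y_holdout)`` instead. The returned table carries the
    raw importance, a sum-normalized share of the positive importances,
    and the rank.
    """
    check_is_fitted(forest, "trees_")
    rng = np.random.default_rng(seed)
    factors = list(table.factor_groups)
    sums = dict.fromkeys(factors, 0.0)
    for tree, hold in zip(forest.trees_, forest.holdout_sets_):
        Xh = table.X[hold]
        yh = table.y[hold]
        mse = float(np.mean((tree.predict(Xh) - yh) ** 2))
        var = float(np.var(yh))
        for f in factors:
            cols = table.factor_groups[f]
            perm = rng.permutation(len(hold))
            Xp = Xh.copy()
            Xp[:, cols] = Xh[np.ix_(perm, cols)]
            mse_star = float(np.mean((tree.predict(Xp) - yh) ** 2))
            if mse > 0:
                sums[f] += (mse_star - mse) / mse
            elif var > 0:  # perfect tree: scale by holdout response variance
                sums[f] += mse_star / var
    imp = {f: sums[f] / len(forest.trees_) for f in factors}
    pos_total = sum(v for v in imp.values() if v > 0)
    df = pd.DataFrame({
        "factor": factors,
        "importance": [imp[f] for f in factors],
        "share": [max(imp[f], 0.0) / pos_total if pos_total > 0 else 0.0
                  for f in factors],
    }).sort_values("importance", ascending=False, ignore_index=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def stack_features(stack: PredictorStack, feature_names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """(X, valid_mask) for every fully valid cell, matching a trained layout.

    Raises with the offending layer names when the stack does not cover
    the trained feature set.
    """
    valid = stack.valid_mask
    needed = []
    for fn in feature_names:
        base = fn.split("=")[0]
        if base.endswith("_sin") or base.endswith("_cos"):
            base = base[:-4]
        needed.append(base)
    missing = sorted({b for b in needed if b not in stack.layers})
    if missing:
        raise ValueError(f"predictor stack lacks layers required by the model: {missing}")
    cols = []
    for fn in feature_names:
        if "=" in fn:
            layer, cls = fn.split("=")
            cols.append((stack[layer].values[valid] == float(cls)).astype(float))
        elif fn.endswith("_sin"):
            cols.append(np.sin(np.radians(stack[fn[:-4]].values[valid])))
        elif fn.endswith("_cos"):
            cols.append(np.cos(np.radians(stack[fn[:-4]].values[valid])))
        else:
            cols.append(stack[fn].values[valid])
    return np.column_stack(cols), valid


def predict_tch(forest: HoldoutForestRegressor, stack: PredictorStack,
                feature_names: list[str]) -> RasterGrid:
    """Wall-to-wall mean-of-trees TCH prediction, clamped at zero.

    Cells with any invalid predictor become nodata.
    """
    X, valid = stack_features(stack, feature_names)
    pred = np.maximum(forest.predict(X), 0.0)
    out = np.full(stack.grid.shape, np.nan)
    out[valid] = pred
    return stack.grid.copy_with(out)
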
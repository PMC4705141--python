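import numpy as np
import pytest

from islandcarbon.raster import RasterGrid
from islandcarbon.rfml import (HoldoutForestRegressor, TrainingTable,
                               assemble_training, factor_importance, predict_tch)
from islandcarbon.stack import PredictorStack


def tiny_stack(shape=(10, 10), seed=0, nan_at=None):
    """A reduced 3-layer stack (two continuous, one categorical)."""
    rng = np.random.default_rng(seed)

    def grid(v):
        return RasterGrid(v, origin=(0.0, shape[0] * 30.0), cell_size=30.0)

    fc = rng.random(shape)
    mapl = 1000 + 500 * rng.random(shape)
    veg = rng.integers(1, 7, shape).astype(float)
    if nan_at is not None:
        mapl[nan_at] = np.nan
    layers = {"FC": grid(fc), "MAP": grid(mapl), "veg_type": grid(veg)}
    roles = {"FC": "continuous", "MAP": "continuous", "veg_type": "categorical"}
    return PredictorStack(layers, roles)


class TestAssembleTraining:
    def test_full_grid_yields_one_row_per_cell(self):
        stack = tiny_stack()
        tch = stack.grid.copy_with(np.random.default_rng(1).random((10, 10)) * 20)
        table = assemble_training(tch, stack)
        assert len(table) == 100

    def test_any_nodata_layer_excludes_the_cell(self):
        stack = tiny_stack(nan_at=(2, 3))
        tch = stack.grid.copy_with(np.full((10, 10), 5.0))
        table = assemble_training(tch, stack)
        assert len(table) == 99
        assert (2 * 10 + 3) not in set(table.cell_index)

    def test_categorical_layer_one_hot_expanded_and_grouped(self, scene):
        tch = scene.canopy_coarse
        table = assemble_training(tch, scene.stack)
        veg_cols = [n for n in table.feature_names if n.startswith("veg_type=")]
        assert len(veg_cols) == 6
        assert len(table.factor_groups["veg_type"]) == 6
        assert table.factor_groups["aspect"] == [
            table.feature_names.index("aspect_sin"),
            table.feature_names.index("aspect_cos")]
        assert len(table.factor_groups) == 17

    def test_all_nodata_is_an_error(self):
        stack = tiny_stack()
        tch = stack.grid.copy_with(np.full((10, 10), np.nan))
        with pytest.raises(ValueError, match="no cells"):
            assemble_training(tch, stack)


class TestForest:
    def test_constant_response_predicts_the_constant(self):
        rng = np.random.default_rng(0)
        X = rng.random((400, 5))
        y = np.full(400, 3.25)
        f = HoldoutForestRegressor(n_trees=20, random_state=0).fit(X, y)
        assert np.allclose(f.predict(X), 3.25)

    def test_same_seed_reproduces_predictions_bit_for_bit(self):
        rng = np.random.default_rng(1)
        X = rng.random((500, 6))
        y = X @ np.arange(6.0) + rng.normal(0, 0.1, 500)
        a = HoldoutForestRegressor(n_trees=30, random_state=7).fit(X, y)
        b = HoldoutForestRegressor(n_trees=30, random_state=7).fit(X, y)
        assert np.array_equal(a.predict(X), b.predict(X))
        assert all(np.array_equal(h1, h2)
                   for h1, h2 in zip(a.holdout_sets_, b.holdout_sets_))

    def test_holdouts_disjoint_from_training_and_sized_250(self):
        rng = np.random.default_rng(2)
        X = rng.random((600, 4))
        y = rng.random(600)
        f = HoldoutForestRegressor(n_trees=10, random_state=3).fit(X, y)
        assert all(len(h) == 250 for h in f.holdout_sets_)

    def test_small_table_shrinks_holdout_with_warning(self):
        rng = np.random.default_rng(3)
        X = rng.random((100, 4))
        y = rng.random(100)
        with pytest.warns(UserWarning, match="shrinking"):
            f = HoldoutForestRegressor(n_trees=5, random_state=0).fit(X, y)
        assert all(len(h) == 20 for h in f.holdout_sets_)

    def test_predictions_bounded_by_training_response(self):
        rng = np.random.default_rng(4)
        X = rng.random((500, 5))
        y = rng.uniform(-3, 9, 500)
        f = HoldoutForestRegressor(n_trees=25, random_state=1).fit(X, y)
        pred = f.predict(rng.random((200, 5)) * 4 - 2)  # outside training box
        assert pred.min() >= y.min() - 1e-9
        assert pred.max() <= y.max() + 1e-9

    def test_noise_free_scene_self_prediction(self, oracle_scene):
        table = assemble_training(oracle_scene.canopy_coarse, oracle_scene.stack)
        f = HoldoutForestRegressor(n_trees=100, random_state=0).fit(table.X, table.y)
        r2 = f.score(table.X, table.y)
        assert r2 >= 0.95

    def test_agrees_with_reference_forest_implementation(self, oracle_scene):
        # independent cross-check: sklearn's bagged-forest on the same table
        from sklearn.ensemble import RandomForestRegressor

        table = assemble_training(oracle_scene.canopy_coarse, oracle_scene.stack)
        ours = HoldoutForestRegressor(n_trees=150, random_state=0).fit(table.X, table.y)
        ref = RandomForestRegressor(n_estimators=150, max_features=1 / 3,
                                    min_samples_leaf=5, random_state=0)
        ref.fit(table.X, table.y)
        r = np.corrcoef(ours.predict(table.X), ref.predict(table.X))[0, 1]
        assert r > 0.95


class TestImportance:
    def make_table(self, n=800, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.random((n, 6))
        y = 10 * X[:, 0] + 4 * X[:, 1] + rng.normal(0, 0.5, n)
        names = [f"f{i}" for i in range(6)]
        groups = {name: [i] for i, name in enumerate(names)}
        return TrainingTable(X, y, names, groups, np.arange(n), (n, 1))

    def test_exact_copy_predictor_ranks_first(self):
        rng = np.random.default_rng(1)
        X = rng.random((600, 4))
        y = X[:, 2].copy()
        names = [f"f{i}" for i in range(4)]
        table = TrainingTable(X, y, names, {n: [i] for i, n in enumerate(names)},
                              np.arange(600), (600, 1))
        f = HoldoutForestRegressor(n_trees=40, random_state=2).fit(X, y)
        imp = factor_importance(f, table, seed=0)
        assert imp.factor.iloc[0] == "f2"

    def test_constant_column_has_exactly_zero_importance(self):
        # permuting a constant column is the identity permutation
        table = self.make_table()
        table.X[:, 5] = 1.0
        f = HoldoutForestRegressor(n_trees=20, random_state=3).fit(table.X, table.y)
        imp = factor_importance(f, table, seed=1).set_index("factor")
        assert imp.loc["f5", "importance"] == 0.0

    def test_report_is_reproducible_under_fixed_seed(self):
        table = self.make_table()
        f = HoldoutForestRegressor(n_trees=15, random_state=4).fit(table.X, table.y)
        a = factor_importance(f, table, seed=9)
        b = factor_importance(f, table, seed=9)
        assert a.equals(b)

    def test_shares_normalize_over_positive_importances(self):
        table = self.make_table()
        f = HoldoutForestRegressor(n_trees=25, random_state=5).fit(table.X, table.y)
        imp = factor_importance(f, table, seed=2)
        assert imp["share"].sum() == pytest.approx(1.0)
        assert (imp["share"] >= 0).all()


class TestPredictTch:
    def test_nodata_cell_propagates_and_output_clamped(self):
        stack = tiny_stack(nan_at=(4, 4))
        tch = stack.grid.copy_with(np.random.default_rng(0).random((10, 10)) * 15)
        table = assemble_training(tch, stack)
        f = HoldoutForestRegressor(n_trees=10, random_state=0).fit(table.X, table.y)
        pred = predict_tch(f, stack, table.feature_names)
        assert np.isnan(pred.values[4, 4])
        assert np.nanmin(pred.values) >= 0.0

    def test_missing_layer_named_in_error(self):
        stack = tiny_stack()
        tch = stack.grid.copy_with(np.random.default_rng(0).random((10, 10)))
        table = assemble_training(tch, stack)
        f = HoldoutForestRegressor(n_trees=5, random_state=0).fit(table.X, table.y)
        smaller = PredictorStack({"FC": stack["FC"], "MAP": stack["MAP"]},
                                 {"FC": "continuous", "MAP": "continuous"})
        with pytest.raises(ValueError, match="veg_type"):
            predict_tch(f, smaller, table.feature_names)

    def test_noise_free_scene_prediction_error_small(self, oracle_scene):
        table = assemble_training(oracle_scene.canopy_coarse, oracle_scene.stack)
        f = HoldoutForestRegressor(n_trees=150, random_state=1).fit(table.X, table.y)
        pred = predict_tch(f, oracle_scene.stack, table.feature_names)
        truth = oracle_scene.canopy_coarse.values
        rng_span = truth.max() - truth.min()
        rmse = np.sqrt(np.nanmean((pred.values - truth) ** 2))
        assert rmse < 0.10 * rng_span

    def test_noise_predictors_do_not_degrade_holdout_fit(self, oracle_scene):
        table = assemble_training(oracle_scene.canopy_coarse, oracle_scene.stack)
        rng = np.random.default_rng(6)
        Xn = np.column_stack([table.X, rng.standard_normal((len(table.y), 3))])
        base = HoldoutForestRegressor(n_trees=80, random_state=2).fit(table.X, table.y)
        noisy = HoldoutForestRegressor(n_trees=80, random_state=2).fit(Xn, table.y)
        # scores on fresh index draws of the same cells
        r2_base = base.score(table.X, table.y)
        r2_noisy = noisy.score(Xn, table.y)
        assert r2_base - r2_noisy <= 0.05
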
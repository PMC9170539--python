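import numpy as np
import pandas as pd
import pytest

from camsdm.envelope import PARealization
from camsdm.grid import RasterStack
from camsdm.modeling import (
    ALGORITHMS,
    LearnerSpec,
    ModelRun,
    fit_and_score,
    make_dataset,
    project_map,
    split_train_test,
)

from conftest import constant_layer, layer_of, small_grid

FAST = {"n_estimators": 30}


def separable_table(n=100, seed=0):
    rng = np.random.default_rng(seed)
    x = np.r_[rng.uniform(0, 0.4, n), rng.uniform(0.6, 1.0, n)]
    return pd.DataFrame(
        {
            "lon": rng.uniform(0, 5, 2 * n),
            "lat": rng.uniform(5, 10, 2 * n),
            "label": np.r_[np.zeros(n, int), np.ones(n, int)],
            "x": x,
        }
    )


class TestLearnerSpec:
    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ValueError):
            LearnerSpec(algorithm="maxent")

    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_builds_a_classifier(self, algo):
        model = LearnerSpec(algorithm=algo, seed=0).build()
        assert hasattr(model, "predict_proba")


class TestMakeDataset:
    def make_inputs(self, grid):
        stack = RasterStack([constant_layer(grid, 3.0, "a")])
        pres = pd.DataFrame({"lon": [0.5, 1.5], "lat": [9.5, 9.5], "a": [3.0, 3.0]})
        lon, lat = grid.cell_center([2, 2], [0, 1])
        pa = PARealization(
            index=1, seed=0, points=pd.DataFrame({"lon": lon, "lat": lat, "row": [2, 2], "col": [0, 1]})
        )
        return stack, pres, pa

    def test_construction_and_label_sum(self, grid):
        stack, pres, pa = self.make_inputs(grid)
        table = make_dataset(pres, pa, stack)
        assert len(table) == 4
        assert table["label"].sum() == 2
        assert list(table.columns) == ["lon", "lat", "label", "a"]

    def test_pa_on_nodata_dropped_and_reported(self, grid):
        vals = np.full(grid.shape, 3.0)
        vals[2, 0] = np.nan
        stack = RasterStack([layer_of(grid, vals, "a")])
        _, pres, pa = self.make_inputs(grid)
        table = make_dataset(pres, pa, stack)
        assert table.attrs["imbalance"] == 1
        assert (table["label"] == 0).sum() == 1

    def test_empty_side_errors(self, grid):
        stack, pres, pa = self.make_inputs(grid)
        with pytest.raises(ValueError):
            make_dataset(pres.iloc[:0], pa, stack)


class TestSplit:
    def test_60_40_stratified_counts(self):
        table = separable_table(n=100)
        train, test = split_train_test(table, 0.6, seed=0)
        labels = table["label"].to_numpy()
        assert len(train) == 120 and len(test) == 80
        assert labels[train].sum() == 60
        assert labels[test].sum() == 40
        assert len(np.intersect1d(train, test)) == 0

    def test_deterministic(self):
        table = separable_table()
        a = split_train_test(table, seed=5)
        b = split_train_test(table, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_degenerate_fractions_rejected(self):
        table = separable_table()
        with pytest.raises(ValueError):
            split_train_test(table, train_fraction=1.0)
        with pytest.raises(ValueError):
            split_train_test(table, train_fraction=0.0)

    def test_tiny_class_rejected(self):
        table = separable_table(n=3)
        with pytest.raises(ValueError):
            split_train_test(table)


class TestFitAndScore:
    @pytest.mark.parametrize("algo", ALGORITHMS)
    def test_separable_toy_is_perfect(self, algo):
        table = separable_table(n=50)
        run = ModelRun(LearnerSpec(algo, seed=0, hyperparameters=FAST), pa_index=1, repeat_index=1)
        fit_and_score(run, table, split_seed=0)
        assert run.scores["roc_auc"] == pytest.approx(1.0)
        assert run.scores["tss"] == pytest.approx(1.0)

    def test_pure_noise_auc_near_half(self):
        rng = np.random.default_rng(1)
        n = 1000
        table = pd.DataFrame(
            {
                "lon": rng.uniform(0, 5, n),
                "lat": rng.uniform(5, 10, n),
                "label": rng.integers(0, 2, n),
                "x": rng.uniform(0, 1, n),
            }
        )
        run = ModelRun(LearnerSpec("boosted_trees", seed=0, hyperparameters=FAST), 1, 1)
        fit_and_score(run, table, split_seed=0)
        assert abs(run.scores["roc_auc"] - 0.5) < 0.1

    def test_scores_computed_on_held_out_rows_only(self):
        table = separable_table(n=50)
        run = ModelRun(LearnerSpec("random_forest", seed=0, hyperparameters=FAST), 1, 1)
        fit_and_score(run, table, split_seed=0)
        assert len(run.test_idx) == 40
        assert set(run.test_idx).isdisjoint(run.train_idx)


class TestProjectMap:
    def fitted_run(self, grid):
        table = separable_table(n=50)
        table = table.rename(columns={"x": "a"})
        run = ModelRun(LearnerSpec("random_forest", seed=0, hyperparameters=FAST), 1, 1)
        fit_and_score(run, table, split_seed=0)
        return run

    def test_constant_stack_gives_constant_map(self, grid):
        run = self.fitted_run(grid)
        stack = RasterStack([constant_layer(grid, 0.8, "a")])
        out = project_map(run, stack)
        assert np.allclose(out.values, out.values[0, 0])
        assert 0.0 <= out.values[0, 0] <= 1.0

    def test_probability_bounds_and_nodata(self, grid):
        run = self.fitted_run(grid)
        vals = np.linspace(0, 1, grid.n_rows * grid.n_cols).reshape(grid.shape)
        vals[0, 0] = np.nan
        stack = RasterStack([layer_of(grid, vals, "a")])
        out = project_map(run, stack)
        assert np.isnan(out.values[0, 0])
        finite = out.values[np.isfinite(out.values)]
        assert np.all((finite >= 0) & (finite <= 1))

    def test_missing_layer_errors(self, grid):
        run = self.fitted_run(grid)
        stack = RasterStack([constant_layer(grid, 1.0, "b")])
        with pytest.raises(KeyError):
            project_map(run, stack)

    def test_identical_seed_and_data_identical_maps(self, grid):
        a = self.fitted_run(grid)
        b = self.fitted_run(grid)
        stack = RasterStack([constant_layer(grid, 0.3, "a")])
        assert np.array_equal(project_map(a, stack).values, project_map(b, stack).values)
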
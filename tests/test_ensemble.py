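import numpy as np
import pandas as pd
import pytest

from camsdm.ensemble import (
    EnsembleModel,
    compute_weights,
    cv_map,
    ensemble_evaluate,
    ensemble_predict,
    standardize_importance,
    variable_importance,
    weighted_mean_map,
)
from camsdm.modeling import LearnerSpec, ModelRun

from conftest import constant_layer, layer_of, small_grid


def scored_member(tss_val, roc_val):
    run = ModelRun(LearnerSpec("random_forest"), 1, 1)
    run.scores = {"tss": tss_val, "roc_auc": roc_val}
    return run


class TestWeights:
    def test_proportional_to_tss(self):
        w = compute_weights([scored_member(0.9, 0.9), scored_member(0.3, 0.8)])
        assert w == pytest.approx([0.75, 0.25])

    def test_roc_exactly_half_excluded(self):
        w = compute_weights([scored_member(0.9, 0.9), scored_member(0.9, 0.5)])
        assert w == pytest.approx([1.0, 0.0])

    def test_equal_scores_uniform(self):
        w = compute_weights([scored_member(0.5, 0.9)] * 4)
        assert w == pytest.approx([0.25] * 4)

    def test_negative_tss_clamped(self):
        w = compute_weights([scored_member(-0.2, 0.9), scored_member(0.4, 0.9)])
        assert w == pytest.approx([0.0, 1.0])

    def test_no_member_passes_errors(self):
        with pytest.raises(ValueError):
            compute_weights([scored_member(0.9, 0.4)])

    def test_weights_sum_to_one(self):
        w = compute_weights([scored_member(t, 0.9) for t in (0.1, 0.5, 0.7, 0.2)])
        assert w.sum() == pytest.approx(1.0, abs=1e-12)


class TestWeightedMeanMap:
    def test_equal_weights_average(self, grid):
        maps = [constant_layer(grid, 0.2, "a"), constant_layer(grid, 0.8, "b")]
        out = weighted_mean_map(maps, np.array([0.5, 0.5]))
        assert np.allclose(out.values, 0.5)

    def test_unequal_weights(self, grid):
        maps = [constant_layer(grid, 0.2, "a"), constant_layer(grid, 0.8, "b")]
        out = weighted_mean_map(maps, np.array([0.75, 0.25]))
        assert np.allclose(out.values, 0.35)

    def test_single_member_identity(self, grid):
        out = weighted_mean_map([constant_layer(grid, 0.42, "a")], np.array([1.0]))
        assert np.allclose(out.values, 0.42)

    def test_convexity_and_nodata(self, grid):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, grid.shape)
        b = rng.uniform(0, 1, grid.shape)
        b[0, 0] = np.nan
        maps = [layer_of(grid, a, "a"), layer_of(grid, b, "b")]
        out = weighted_mean_map(maps, np.array([0.3, 0.7]))
        assert np.isnan(out.values[0, 0])
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        ok = np.isfinite(out.values)
        assert np.all(out.values[ok] >= lo[ok] - 1e-12)
        assert np.all(out.values[ok] <= hi[ok] + 1e-12)

    def test_bad_weights_rejected(self, grid):
        maps = [constant_layer(grid, 0.2, "a"), constant_layer(grid, 0.8, "b")]
        with pytest.raises(ValueError):
            weighted_mean_map(maps, np.array([0.5, 0.6]))


class TestCVMap:
    def test_identical_members_zero(self, grid):
        out = cv_map([constant_layer(grid, 0.4, "a"), constant_layer(grid, 0.4, "b")])
        assert np.allclose(out.values, 0.0)

    def test_hand_arithmetic(self, grid):
        # values 0.4, 0.6: sd = sqrt(0.02), mean = 0.5 -> 28.2843%
        out = cv_map([constant_layer(grid, 0.4, "a"), constant_layer(grid, 0.6, "b")])
        assert np.allclose(out.values, 28.284271, atol=1e-5)

    def test_scale_invariance(self, grid):
        rng = np.random.default_rng(3)
        a, b = rng.uniform(0.1, 1, grid.shape), rng.uniform(0.1, 1, grid.shape)
        cv1 = cv_map([layer_of(grid, a, "a"), layer_of(grid, b, "b")]).values
        cv2 = cv_map([layer_of(grid, 3 * a, "a"), layer_of(grid, 3 * b, "b")]).values
        assert np.allclose(cv1, cv2)

    def test_zero_mean_masked(self, grid):
        out = cv_map([constant_layer(grid, 0.0, "a"), constant_layer(grid, 0.0, "b")])
        assert np.all(np.isnan(out.values))

    def test_single_member_rejected(self, grid):
        with pytest.raises(ValueError):
            cv_map([constant_layer(grid, 0.4, "a")])


class TestEnsembleEvaluate:
    def test_perfect_members_give_perfect_ensemble(self, toy_ensemble):
        members, table = toy_ensemble
        weights = compute_weights(members)
        scores, cutoff = ensemble_evaluate(members, weights, [table, table])
        assert scores["tss"] > 0.9
        assert 0.0 <= cutoff <= 1.0

    def test_prediction_within_member_envelope(self, toy_ensemble):
        members, table = toy_ensemble
        weights = np.array([0.4, 0.6])
        ens = ensemble_predict(members, weights, table)
        per_member = np.stack([m.predict(table) for m in members])
        assert np.all(ens >= per_member.min(axis=0) - 1e-12)
        assert np.all(ens <= per_member.max(axis=0) + 1e-12)


class TestImportance:
    def make_model(self, toy_ensemble):
        members, table = toy_ensemble
        weights = compute_weights(members)
        return EnsembleModel(members=members, weights=weights), table

    def test_unused_predictor_scores_zero(self, toy_ensemble):
        model, table = self.make_model(toy_ensemble)
        imp = variable_importance(model, table, n_shuffles=3, seed=0)
        assert imp.loc["x2", "raw"] == 0.0
        assert imp.loc["x1", "pct"] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self, toy_ensemble):
        model, table = self.make_model(toy_ensemble)
        imp = variable_importance(model, table, n_shuffles=3, seed=1)
        assert imp["pct"].sum() == pytest.approx(100.0)

    def test_deterministic_under_seed(self, toy_ensemble):
        model, table = self.make_model(toy_ensemble)
        a = variable_importance(model, table, n_shuffles=3, seed=9)
        b = variable_importance(model, table, n_shuffles=3, seed=9)
        assert a.equals(b)

    def test_proportional_standardization(self):
        raw = pd.Series({"a": 0.02, "b": 0.74, "c": 0.20, "d": 0.04})
        pct = standardize_importance(raw)
        assert pct.to_list() == pytest.approx([2.0, 74.0, 20.0, 4.0])

    def test_all_zero_raw_stays_zero(self):
        pct = standardize_importance(pd.Series({"a": 0.0, "b": 0.0}))
        assert pct.sum() == 0.0
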
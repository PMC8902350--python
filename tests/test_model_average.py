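from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from treemort.model_average import (
    AICModelAverager,
    aic_weights,
    averaged_estimate,
    enumerate_models,
    select_group,
    select_radius,
    variable_importance,
)


class TestEnumerateModels:
    def test_empty_candidate_set_gives_null_model_only(self):
        assert enumerate_models([]) == [()]

    def test_three_candidates_give_eight_subsets(self):
        models = enumerate_models(["a", "b", "c"])
        assert len(models) == 8
        assert models[0] == ()
        assert set(models) == {
            (), ("a",), ("b",), ("a", "b"), ("c",), ("a", "c"), ("b", "c"),
            ("a", "b", "c"),
        }

    def test_eleven_candidates_give_2048(self):
        assert len(enumerate_models(list("abcdefghijk"))) == 2048

    def test_guard_refuses_oversized_sets(self):
        with pytest.raises(ValueError, match="2\\^17"):
            enumerate_models([f"v{i}" for i in range(17)])


class TestAicWeights:
    def test_equal_aics_split_evenly(self):
        np.testing.assert_allclose(aic_weights([100.0, 100.0]), [0.5, 0.5])

    def test_two_unit_gap(self):
        w = aic_weights([100.0, 102.0])
        expected = np.array([1.0, np.exp(-1.0)])
        expected /= expected.sum()
        np.testing.assert_allclose(w, expected, atol=1e-10)
        assert w[0] == pytest.approx(0.7311, abs=1e-4)
        assert w[1] == pytest.approx(0.2689, abs=1e-4)

    @given(st.lists(st.floats(-1e4, 1e4), min_size=1, max_size=20))
    def test_sum_to_one_and_shift_invariant(self, aics):
        w = aic_weights(aics)
        assert w.sum() == pytest.approx(1.0)
        w2 = aic_weights(np.asarray(aics) + 123.4)
        np.testing.assert_allclose(w, w2, atol=1e-12)


class TestVariableImportance:
    def test_always_present_variable_has_importance_one(self):
        mv = [("a",), ("a", "b")]
        imp = variable_importance(mv, [0.6, 0.4])
        assert imp["a"] == pytest.approx(1.0)
        assert imp["b"] == pytest.approx(0.4)

    def test_equal_weights_two_vars(self):
        mv = [(), ("a",), ("b",), ("a", "b")]
        imp = variable_importance(mv, [0.25] * 4)
        assert imp == {"a": pytest.approx(0.5), "b": pytest.approx(0.5)}


class TestSelectGroup:
    def test_unique_best_far_ahead(self):
        mask = select_group([10.0, 13.0, 14.0])
        assert mask.tolist() == [True, False, False]

    def test_boundary_inclusive_at_delta(self):
        mask = select_group([10.0, 11.9, 12.1])
        assert mask.tolist() == [True, True, False]

    def test_all_equal_keeps_all(self):
        assert select_group([5.0, 5.0, 5.0]).all()


class TestAveragedEstimate:
    def test_single_model_degenerate(self):
        b, se = averaged_estimate([0.7], [0.12], [1.0])
        assert (b, se) == (pytest.approx(0.7), pytest.approx(0.12))

    def test_two_model_hand_example(self):
        b, se = averaged_estimate([0.4, 0.6], [0.1, 0.1], [0.5, 0.5])
        assert b == pytest.approx(0.5, abs=1e-12)
        assert se == pytest.approx(0.5 * 2 * np.sqrt(0.01 + 0.01), abs=1e-12)
        assert se == pytest.approx(0.141421356, abs=1e-9)

    def test_identical_betas_reduce_to_weighted_mean_se(self):
        b, se = averaged_estimate([0.3, 0.3, 0.3], [0.1, 0.2, 0.3], [0.5, 0.3, 0.2])
        assert b == pytest.approx(0.3)
        assert se == pytest.approx(0.5 * 0.1 + 0.3 * 0.2 + 0.2 * 0.3)

    def test_natural_averaging_renormalizes_over_containing_models(self):
        b, _ = averaged_estimate([0.4, np.nan], [0.1, np.nan], [0.5, 0.5])
        assert b == pytest.approx(0.4)

    def test_full_averaging_shrinks_toward_zero(self):
        b, _ = averaged_estimate([0.4, np.nan], [0.1, np.nan], [0.5, 0.5], mode="full")
        assert b == pytest.approx(0.2)

    def test_var_in_no_model_undefined(self):
        b, se = averaged_estimate([np.nan], [np.nan], [1.0])
        assert np.isnan(b) and np.isnan(se)


class TestAveragerEndToEnd:
    def _data(self, n=3000, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            {
                "strong": rng.standard_normal(n),
                "weak": rng.standard_normal(n),
                "null": rng.standard_normal(n),
            }
        )
        sp = rng.integers(0, 10, n)
        gr = rng.integers(0, 50, n)
        eta = (
            -1.5 + 0.8 * X["strong"].to_numpy() + 0.25 * X["weak"].to_numpy()
            + rng.normal(0, 0.3, 10)[sp] + rng.normal(0, 0.2, 50)[gr]
        )
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        return X, y, sp, gr

    def test_model_count_and_weight_normalization(self):
        X, y, sp, gr = self._data()
        est = AICModelAverager().fit(X, y, species=sp, grid=gr)
        assert len(est.models_) + est.n_dropped_ == 8
        assert est.weights_.sum() == pytest.approx(1.0)
        assert all(0.0 <= v <= 1.0 for v in est.importance_.values())

    def test_strong_effect_recovered_and_significant(self):
        X, y, sp, gr = self._data()
        est = AICModelAverager().fit(X, y, species=sp, grid=gr)
        res = est.results_
        assert res.loc["strong", "importance"] > 0.99
        assert res.loc["strong", "significant"]
        assert res.loc["strong", "beta_avg"] == pytest.approx(0.8, abs=0.15)
        assert abs(res.loc["null", "beta_avg"]) < 0.15 or np.isnan(
            res.loc["null", "beta_avg"]
        )

    def test_null_variable_importance_dilutes(self):
        # a covariate with no effect should rarely look important
        hits = 0
        reps = 8
        for rep in range(reps):
            X, y, sp, gr = self._data(n=1500, seed=50 + rep)
            est = AICModelAverager().fit(
                X[["null", "strong"]], y, species=sp, grid=gr
            )
            if est.results_.loc["null", "importance"] < 0.6:
                hits += 1
        assert hits >= int(0.8 * reps) - 1


class TestSelectRadius:
    def test_single_candidate_radius_returned(self, small_census):
        from treemort.neighborhood import stratified_indices

        df = small_census
        ni = stratified_indices(df, df, radii=[10])
        sel = select_radius(
            ni, df["dead"].to_numpy(), df["species"].to_numpy(),
            df["grid_id"].to_numpy(), radii=[10],
        )
        assert sel.radius == 10.0
        assert list(sel.aic_curve.columns) == ["radius", "aic", "converged"]
        assert len(sel.aic_curve) == 1
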
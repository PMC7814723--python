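import numpy as np
import pandas as pd
import pytest

import healthreach as hr
from healthreach import modeling as M


def synth_table(n=800, seed=0, groups=6, b_pov=2.0, b_dens=-3.0, b_int=0.0, noise=1.0):
    """Tabular data with known coefficients for model-recovery checks."""
    rng = np.random.default_rng(seed)
    pov = rng.uniform(0, 1, n)
    dens = rng.lognormal(5, 1, n)
    sub = rng.integers(0, groups, n)
    group_eff = rng.normal(0, 1.0, groups)
    dens_s = (np.log(dens) - np.log(dens).mean()) / np.log(dens).std()
    pov_s = pov - pov.mean()
    y = (
        b_pov * pov_s
        + b_dens * dens_s
        + b_int * pov_s * dens_s
        + group_eff[sub]
        + rng.normal(0, noise, n)
    )
    return pd.DataFrame(
        {"poverty": pov, "density": dens, "subregion": sub, "y": y}
    )


class TestSplit:
    def test_standard_split_sizes(self):
        tab = pd.DataFrame({"a": np.arange(5000)})
        tr, te = M.split(tab, 0.85, seed=1)
        assert (len(tr), len(te)) == (4250, 750)

    def test_degenerate_fraction_rejected(self):
        with pytest.raises(ValueError):
            M.split(pd.DataFrame({"a": [1, 2]}), 1.0)

    def test_union_is_original(self):
        tab = pd.DataFrame({"a": np.arange(100)})
        tr, te = M.split(tab, 0.7, seed=3)
        assert sorted(tr["a"].tolist() + te["a"].tolist()) == list(range(100))


class TestVifScreen:
    def test_independent_predictors_vif_near_one(self):
        rng = np.random.default_rng(0)
        tab = pd.DataFrame({"a": rng.normal(size=1000), "b": rng.normal(size=1000)})
        kept, vifs = M.vif_screen(tab, ["a", "b"])
        assert kept == ["a", "b"]
        assert vifs["a"] == pytest.approx(1.0, abs=0.1)
        assert vifs["b"] == pytest.approx(1.0, abs=0.1)

    def test_duplicated_predictor_removed(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=200)
        tab = pd.DataFrame({"a": a, "dup": a.copy(), "c": rng.normal(size=200)})
        with pytest.warns(UserWarning, match="dropping"):
            kept, _ = M.vif_screen(tab, ["a", "dup", "c"])
        assert "c" in kept and len(kept) == 2


class TestSamplePoints:
    def test_row_count_and_mask_membership(self, recovery_scene, recovery_table):
        assert len(recovery_table) == 4000
        rr, cc = recovery_scene.grid.xy_to_rowcol(
            recovery_table["x"].to_numpy(), recovery_table["y"].to_numpy()
        )
        assert recovery_scene.study_mask[rr, cc].all()
        # no missing covariates after extraction
        assert np.isfinite(recovery_table.drop(columns="subregion").to_numpy()).all()

    def test_deterministic_given_seed(self, recovery_scene, small_scene, small_surfaces):
        walk = small_surfaces["walk"]
        bike = small_surfaces["bicycle"]
        t1 = M.sample_points(small_scene, walk, bike, n=200, seed=9)
        t2 = M.sample_points(small_scene, walk, bike, n=200, seed=9)
        pd.testing.assert_frame_equal(t1, t2)


class TestTukeyTransform:
    def test_normal_sample_lambda_near_one(self):
        x = np.random.default_rng(0).normal(10, 1, 3000)
        tf, _ = M.tukey_transform(x)
        assert abs(tf.lmbda - 1.0) <= 0.25

    def test_lognormal_sample_lambda_near_zero(self):
        x = np.random.default_rng(1).lognormal(0, 1, 3000)
        tf, _ = M.tukey_transform(x)
        assert abs(tf.lmbda) <= 0.25

    def test_output_centered_exactly(self):
        x = np.random.default_rng(2).gamma(2, 2, 500)
        _, t = M.tukey_transform(x)
        assert abs(t.mean()) < 1e-10

    def test_nonpositive_input_shifted_with_warning(self):
        x = np.random.default_rng(3).normal(0, 1, 500)
        with pytest.warns(UserWarning, match="shift"):
            tf, t = M.tukey_transform(x)
        assert np.isfinite(t).all()

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            M.tukey_transform(np.ones(50))


class TestForest:
    @pytest.fixture(scope="class")
    def fitted(self, recovery_table):
        tr, te = M.split(recovery_table, 0.85, seed=0)
        res = M.fit_forest(tr, te, "walk_hc2", mtry_grid=(1, 2, 3),
                           ntree_grid=(150,), seed=0)
        return tr, te, res

    def test_selected_hyperparameters_reported(self, fitted):
        _, _, res = fitted
        assert res.hyperparams["mtry"] in (1, 2, 3)
        assert res.hyperparams["ntree"] == 150

    def test_mae_not_above_rmse(self, fitted):
        _, _, res = fitted
        assert res.metrics["MAE"] <= res.metrics["RMSE"]

    def test_empty_grid_rejected(self, recovery_table):
        tr, te = M.split(recovery_table, 0.85, seed=0)
        with pytest.raises(ValueError):
            M.fit_forest(tr, te, "walk_hc2", mtry_grid=(), ntree_grid=(100,))

    def test_importance_ranks_are_permutation(self, fitted):
        tr, _, res = fitted
        imp = M.conditional_importance(res, tr, n_iter=5, seed=0)
        assert sorted(imp["rank"]) == [1, 2, 3]

    def test_noise_predictor_ranks_last(self, recovery_table):
        rng = np.random.default_rng(5)
        tab = recovery_table.assign(noise=rng.normal(size=len(recovery_table)))
        tr, te = M.split(tab, 0.85, seed=0)
        res = M.fit_forest(tr, te, "walk_hc2", mtry_grid=(2,), ntree_grid=(150,),
                           seed=0, predictors=["density", "poverty", "subregion", "noise"])
        imp = M.conditional_importance(res, tr, n_iter=10, seed=0)
        assert imp.loc["noise", "rank"] == 4
        assert imp.loc["noise", "score"] < 0.1 * imp["score"].max()

    def test_averaging_importance_reduces_variance(self, fitted):
        tr, _, res = fitted
        singles = [
            M.conditional_importance(res, tr, n_iter=1, seed=s).loc["poverty", "score"]
            for s in range(8)
        ]
        averaged = [
            M.conditional_importance(res, tr, n_iter=8, seed=100 + s).loc["poverty", "score"]
            for s in range(3)
        ]
        assert np.std(averaged) < np.std(singles) + 1e-9

    def test_partial_dependence_recovers_linear_slope(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 1500)
        other = rng.normal(size=1500)
        tab = pd.DataFrame({"x": x, "other": other, "y": 2.0 * x + rng.normal(0, 0.5, 1500)})
        tr, te = M.split(tab, 0.85, seed=0)
        res = M.fit_forest(tr, te, "y", mtry_grid=(1,), ntree_grid=(150,), seed=0,
                           predictors=["x", "other"])
        grid, curve = M.partial_dependence(res, tr, "x")
        slope = np.polyfit(grid, curve, 1)[0]
        assert slope == pytest.approx(2.0, rel=0.2)

    def test_partial_dependence_grid_respects_boxplot_fences(self, fitted):
        tr, _, res = fitted
        grid, _ = M.partial_dependence(res, tr, "density")
        col = tr["density"].to_numpy()
        q1, q3 = np.percentile(col, [25, 75])
        iqr = q3 - q1
        assert grid.min() >= q1 - 1.5 * iqr - 1e-9
        assert grid.max() <= q3 + 1.5 * iqr + 1e-9


class TestMixedModels:
    def test_five_candidates_fit(self):
        tab = synth_table(seed=0)
        tr, te = M.split(tab, 0.85, seed=0)
        best, results = M.fit_mixed_models(tr, te, "y", seed=0)
        assert len(results) == 5
        fixed_sets = {r.hyperparams["fixed_effects"] for r in results}
        assert () in fixed_sets and ("poverty_t", "density_t", "interaction") in fixed_sets

    def test_bic_selection_invariant_to_order(self):
        tab = synth_table(seed=1)
        tr, te = M.split(tab, 0.85, seed=0)
        best, results = M.fit_mixed_models(tr, te, "y", seed=0)
        assert best.bic == min(r.bic for r in results)

    def test_interaction_recovered_in_majority_of_replicates(self):
        wins = 0
        for seed in range(5):
            tab = synth_table(n=1200, seed=seed, b_int=3.0, noise=0.8)
            tr, te = M.split(tab, 0.85, seed=seed)
            best, _ = M.fit_mixed_models(tr, te, "y", seed=0)
            if "interaction" in best.hyperparams["fixed_effects"]:
                wins += 1
        assert wins >= 3

    def test_positive_poverty_effect_sign_recovered(self):
        tab = synth_table(n=1500, seed=2, b_pov=2.0, noise=0.5)
        tr, te = M.split(tab, 0.85, seed=0)
        best, results = M.fit_mixed_models(tr, te, "y", seed=0)
        mains = next(
            r for r in results
            if r.hyperparams["fixed_effects"] == ("poverty_t", "density_t")
        )
        assert mains.coefficients.loc["poverty_t", "Estimate"] > 0
        assert mains.coefficients.loc["poverty_t", "p"] < 0.05

    def test_icc_and_variance_components_valid(self):
        tab = synth_table(seed=3)
        tr, te = M.split(tab, 0.85, seed=0)
        best, results = M.fit_mixed_models(tr, te, "y", seed=0)
        for r in results:
            vc = r.variance_components
            assert vc["sigma2"] > 0 and vc["tau00"] >= 0
            assert 0 <= vc["ICC"] <= 1
            assert r.metrics["MAE"] <= r.metrics["RMSE"]

    def test_null_model_grouping_check_reported(self):
        tab = synth_table(seed=4)
        tr, te = M.split(tab, 0.85, seed=0)
        _, results = M.fit_mixed_models(tr, te, "y", seed=0)
        null = next(r for r in results if r.hyperparams["fixed_effects"] == ())
        assert null.extra["grouping_lrt_p"] < 0.05  # strong simulated group effects


class TestCompareModels:
    def test_deltas_match_direct_subtraction(self):
        f = M.ModelFitResult(kind="forest", response="r1",
                             metrics={"MAE": 10.0, "RMSE": 12.0, "R2": 0.6})
        m = M.ModelFitResult(kind="mixed", response="r1",
                             metrics={"MAE": 12.0, "RMSE": 15.0, "R2": 0.5})
        out = M.compare_models([f], [m])
        row = out.iloc[0]
        assert row["dMAE"] == pytest.approx(-2.0)
        assert row["dRMSE"] == pytest.approx(-3.0)
        assert row["dR2"] == pytest.approx(0.1)

    def test_identical_predictions_zero_deltas(self):
        f = M.ModelFitResult(kind="forest", response="r",
                             metrics={"MAE": 1.0, "RMSE": 2.0, "R2": 0.9})
        m = M.ModelFitResult(kind="mixed", response="r",
                             metrics={"MAE": 1.0, "RMSE": 2.0, "R2": 0.9})
        out = M.compare_models([f], [m])
        assert (out[["dMAE", "dRMSE", "dR2"]].to_numpy() == 0).all()

    def test_unmatched_responses_rejected(self):
        f = M.ModelFitResult(kind="forest", response="a", metrics={})
        m = M.ModelFitResult(kind="mixed", response="b", metrics={})
        with pytest.raises(ValueError):
            M.compare_models([f], [m])
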
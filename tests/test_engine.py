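"""Prediction engine: grid search, level-1/stacked models, metrics,
importance, and the no-leakage contract."""

import numpy as np
import pandas as pd
import pytest

from brainage_eval.cohort import CohortSpec, FeatureSetSpec, generate_cohort
from brainage_eval.enet import HyperGrid, enet_fit
from brainage_eval.engine import (
    StackSpec,
    assemble_out_of_fold,
    default_stack_specs,
    grid_search,
    importance_stability,
    metrics,
    refit_importance,
    run_level1,
    run_stacking,
)
from brainage_eval.folds import make_fold_scheme
from brainage_eval.prep import apply_preproc, fit_preproc

from conftest import planted_signal_set


class TestMetrics:
    def test_perfect_prediction(self):
        out = metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["r2"] == 1.0
        assert out["mae"] == 0.0

    def test_constant_prediction_r_undefined_r2_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        out = metrics(obs, np.full(4, obs.mean()))
        assert np.isnan(out["pearson_r"])
        assert out["r2"] == pytest.approx(0.0)
        assert out["mae"] == pytest.approx(1.0)

    def test_hand_computed_example(self):
        out = metrics([1, 2, 3, 4], [2, 2, 3, 5])
        assert out["mae"] == pytest.approx(0.5)
        assert out["r2"] == pytest.approx(1 - 2 / 5)

    def test_r2_can_be_negative(self):
        out = metrics([1.0, 2.0, 3.0], [3.0, 3.0, 0.0])
        assert out["r2"] < 0


class TestGridSearch:
    @pytest.fixture()
    def data(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((100, 4))
        y = x @ np.array([1.0, -0.5, 0.0, 0.2]) + 0.3 * rng.standard_normal(100)
        sex = rng.integers(0, 2, 100)
        labels = np.repeat(np.arange(5), 20)
        return x, sex, y, labels

    def test_single_point_grid_returns_that_point(self, data):
        x, sex, y, labels = data
        tuned = grid_search(x, sex, y, labels, HyperGrid.single(0.7, 0.3))
        assert (tuned.alpha, tuned.l1_ratio) == (0.7, 0.3)

    def test_absurd_alpha_loses_to_moderate_alpha(self, data):
        x, sex, y, labels = data
        grid = HyperGrid(alphas=(0.1, 1e6), l1_ratios=(0.5,))
        tuned = grid_search(x, sex, y, labels, grid)
        assert tuned.alpha == 0.1

    def test_selection_matches_brute_force_rescoring(self, data):
        """Winner agrees with an independent exhaustive re-evaluation that
        re-fits every grid point per inner fold from scratch."""
        x, sex, y, labels = data
        grid = HyperGrid(alphas=(0.1, 0.5, 2.0, 8.0, 30.0), l1_ratios=(0.2, 0.8))
        tuned = grid_search(x, sex, y, labels, grid)

        best, best_score = None, -np.inf
        for alpha in grid.alphas:
            for l1 in grid.l1_ratios:
                scores = []
                for f in np.unique(labels):
                    tr, val = labels != f, labels == f
                    pp = fit_preproc(x[tr], sex[tr], kind="direct")
                    xt = apply_preproc(x[tr], sex[tr], pp)
                    xv = apply_preproc(x[val], sex[val], pp)
                    coef, b0 = enet_fit(xt, y[tr], alpha, l1)
                    pred = xv @ coef + b0
                    ss_tot = np.sum((y[val] - y[val].mean()) ** 2)
                    scores.append(1 - np.sum((y[val] - pred) ** 2) / ss_tot)
                mean = np.mean(scores)
                if mean > best_score:
                    best_score, best = mean, (alpha, l1)
        assert (tuned.alpha, tuned.l1_ratio) == best
        assert tuned.validation_score == pytest.approx(best_score, abs=1e-3)

    def test_tie_breaks_to_first_ascending_point(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((50, 2))
        y = rng.standard_normal(50)  # pure noise: huge alphas all tie at ~0 coef
        labels = np.repeat(np.arange(5), 10)
        grid = HyperGrid(alphas=(1e7, 1e8), l1_ratios=(0.5, 1.0))
        tuned = grid_search(x, sex := np.zeros(50), y, labels, grid)
        assert (tuned.alpha, tuned.l1_ratio) == (1e7, 0.5)


@pytest.fixture(scope="module")
def small_run(tiny_cohort_module):
    cohort, feats, truth = tiny_cohort_module
    scheme = make_fold_scheme(cohort.index.to_numpy(), seed=21)
    grid = HyperGrid.reduced()
    level1 = run_level1(feats, cohort, "age", scheme, grid, n_components=10)
    return cohort, feats, truth, scheme, grid, level1


@pytest.fixture(scope="module")
def tiny_cohort_module():
    from brainage_eval.cohort import demo_spec

    return generate_cohort(demo_spec(n_participants=150), seed=11)


class TestLevel1:
    def test_planted_signal_gives_near_perfect_oof_r2(self):
        cohort, table = planted_signal_set(n=120)
        from brainage_eval.cohort import FeatureSetCollection

        feats = FeatureSetCollection({"s": table}, {"s": "direct"}, {"s": "smri"})
        scheme = make_fold_scheme(cohort.index.to_numpy(), seed=1)
        grid = HyperGrid(alphas=(0.001, 0.01, 0.1), l1_ratios=(1.0,))
        level1 = run_level1(feats, cohort, "age", scheme, grid)
        res = assemble_out_of_fold(level1, cohort, "age", scheme)["s"]
        assert res.pooled_metrics()["r2"] > 0.99

    def test_broken_alignment_gives_null_performance(self):
        cohort, table = planted_signal_set(n=120)
        from brainage_eval.cohort import FeatureSetCollection

        rng = np.random.default_rng(99)
        shuffled = cohort.copy()
        shuffled["age_years"] = rng.permutation(shuffled["age_years"].to_numpy())
        feats = FeatureSetCollection({"s": table}, {"s": "direct"}, {"s": "smri"})
        scheme = make_fold_scheme(cohort.index.to_numpy(), seed=1)
        grid = HyperGrid(alphas=(0.001, 0.1, 10.0), l1_ratios=(0.5,))
        level1 = run_level1(feats, shuffled, "age", scheme, grid)
        res = assemble_out_of_fold(level1, shuffled, "age", scheme)["s"]
        assert res.pooled_metrics()["r2"] <= 0.05

    def test_missing_participants_rejected(self, tiny_cohort_module):
        cohort, feats, _ = tiny_cohort_module
        from brainage_eval.cohort import FeatureSetCollection

        name = feats.names[0]
        cropped = FeatureSetCollection(
            {name: feats[name].iloc[:-2]}, {name: "direct"}, {name: "smri"}
        )
        scheme = make_fold_scheme(cohort.index.to_numpy(), seed=2)
        with pytest.raises(ValueError, match="missing participants"):
            run_level1(cropped, cohort, "age", scheme, HyperGrid.reduced())

    def test_every_participant_predicted_once(self, small_run):
        cohort, feats, truth, scheme, grid, level1 = small_run
        res = assemble_out_of_fold(level1, cohort, "age", scheme)
        for r in res.values():
            assert len(r.out_of_fold) == len(cohort)
            assert not r.out_of_fold.index.duplicated().any()

    def test_per_fold_metrics_match_recomputation(self, small_run):
        cohort, feats, truth, scheme, grid, level1 = small_run
        res = assemble_out_of_fold(level1, cohort, "age", scheme)
        name = feats.names[0]
        row = res[name].per_fold_metrics.iloc[2]
        f = int(row["fold"])
        te = scheme.outer_test_ids(f)
        m = metrics(cohort.loc[te, "age_years"], res[name].out_of_fold.loc[te])
        assert row["r2"] == pytest.approx(m["r2"], abs=1e-12)
        assert row["mae"] == pytest.approx(m["mae"], abs=1e-12)


class TestLeakage:
    def test_outer_test_rows_cannot_influence_the_fold_model(self, tiny_cohort_module):
        """Perturbing outer-test rows leaves that fold's preprocessing and
        tuned model bit-identical."""
        cohort, feats, _ = tiny_cohort_module
        scheme = make_fold_scheme(cohort.index.to_numpy(), seed=21)
        grid = HyperGrid(alphas=(0.1, 1.0), l1_ratios=(0.5,))
        name = feats.names[0]
        f = 0
        tr = scheme.outer_train_ids(f)

        def tune(table, coh):
            return grid_search(
                table.loc[tr],
                coh.loc[tr, "sex"].to_numpy(),
                coh.loc[tr, "age_years"].to_numpy(),
                scheme.inner_labels("level1", f),
                grid,
                kind="direct",
            )

        t1 = tune(feats[name], cohort)
        te = scheme.outer_test_ids(f)
        vals = feats[name].to_numpy().copy()
        te_mask = feats[name].index.isin(te)
        vals[te_mask] += 1000.0
        table2 = pd.DataFrame(vals, index=feats[name].index,
                              columns=feats[name].columns)
        coh2 = cohort.copy()
        coh2.loc[te, "age_years"] = 0.0
        t2 = tune(table2, coh2)
        assert (t1.alpha, t1.l1_ratio) == (t2.alpha, t2.l1_ratio)
        # tiny tolerance absorbs memory-layout summation-order noise only;
        # a genuine leak would shift these by orders of magnitude
        np.testing.assert_allclose(t1.coefficients, t2.coefficients,
                                   rtol=1e-10, atol=1e-12)
        assert t1.intercept == pytest.approx(t2.intercept, abs=1e-10)
        np.testing.assert_allclose(
            t1.preproc.feature_means, t2.preproc.feature_means, atol=1e-12
        )
        np.testing.assert_allclose(
            t1.preproc.feature_sds, t2.preproc.feature_sds, rtol=1e-12
        )

    def test_engine_is_deterministic(self, tiny_cohort_module):
        cohort, feats, _ = tiny_cohort_module
        from brainage_eval.cohort import FeatureSetCollection

        name = feats.names[1]
        one = FeatureSetCollection({name: feats[name]},
                                   {name: feats.kinds[name]},
                                   {name: feats.categories[name]})
        grid = HyperGrid(alphas=(0.1, 1.0), l1_ratios=(0.0, 1.0))
        out = []
        for _ in range(2):
            scheme = make_fold_scheme(cohort.index.to_numpy(), seed=5)
            level1 = run_level1(one, cohort, "age", scheme, grid)
            res = assemble_out_of_fold(level1, cohort, "age", scheme)[name]
            out.append(res.out_of_fold)
        pd.testing.assert_series_equal(out[0], out[1])


class TestStacking:
    def test_default_specs_resolve_to_eight_for_full_layout(self):
        cats = {f"c{i}": "task_contrast" for i in range(10)}
        cats |= {f"f{i}": "task_fc" for i in range(3)}
        cats |= {"rest": "rest_fc"}
        cats |= {f"s{i}": "smri" for i in range(4)}
        specs = default_stack_specs(cats)
        assert len(specs) == 8
        by_name = {s.name: s for s in specs}
        assert len(by_name["stacked_all"].member_sets) == 18
        assert len(by_name["stacked_non_task"].member_sets) == 5
        assert len(by_name["stacked_task_fc"].member_sets) == 3

    def test_unknown_member_rejected(self, small_run):
        cohort, feats, truth, scheme, grid, level1 = small_run
        with pytest.raises(ValueError, match="unknown sets"):
            run_stacking(level1, cohort, "age", scheme, grid,
                         [StackSpec("bad", ("nope",))])

    def test_single_member_stack_tracks_the_member(self, small_run):
        cohort, feats, truth, scheme, grid, level1 = small_run
        name = "cortical_thickness"
        stacked = run_stacking(level1, cohort, "age", scheme, grid,
                               [StackSpec("solo", (name,))])
        res_m = assemble_out_of_fold(level1, cohort, "age", scheme)[name]
        res_s = assemble_out_of_fold(stacked, cohort, "age", scheme)["solo"]
        r2_m = res_m.pooled_metrics()["r2"]
        r2_s = res_s.pooled_metrics()["r2"]
        assert r2_s == pytest.approx(r2_m, abs=0.02)

    def test_perfect_member_gives_perfect_stack(self):
        cohort, table = planted_signal_set(n=120)
        from brainage_eval.cohort import FeatureSetCollection

        feats = FeatureSetCollection({"s": table}, {"s": "direct"}, {"s": "smri"})
        scheme = make_fold_scheme(cohort.index.to_numpy(), seed=1)
        grid = HyperGrid(alphas=(0.001, 0.01, 0.1), l1_ratios=(1.0,))
        level1 = run_level1(feats, cohort, "age", scheme, grid)
        stacked = run_stacking(level1, cohort, "age", scheme, grid,
                               [StackSpec("solo", ("s",))])
        res = assemble_out_of_fold(stacked, cohort, "age", scheme)["solo"]
        assert res.pooled_metrics()["r2"] > 0.99

    def test_combining_independent_errors_does_not_hurt(self, small_run):
        """A stack of two sets with independent error sources performs at
        least as well as its best member (small slack)."""
        cohort, feats, truth, scheme, grid, level1 = small_run
        members = ("cortical_thickness", "subcortical_volume")
        stacked = run_stacking(level1, cohort, "age", scheme, grid,
                               [StackSpec("duo", members)])
        res1 = assemble_out_of_fold(level1, cohort, "age", scheme)
        res_s = assemble_out_of_fold(stacked, cohort, "age", scheme)["duo"]
        best = max(res1[m].pooled_metrics()["r2"] for m in members)
        assert res_s.pooled_metrics()["r2"] >= best - 0.02


class TestImportance:
    def test_backprojection_hand_example(self):
        # two components, loadings rows (1,-1)/(1,1), coefficients (2,3)
        load = np.array([[1.0, -1.0], [1.0, 1.0]])
        coef = np.array([2.0, 3.0])
        imp = np.abs(load).T @ coef
        np.testing.assert_allclose(imp, [5.0, 5.0])

    def test_single_component_importance(self):
        load = np.array([[0.5, -2.0, 1.0]])
        coef = np.array([4.0])
        np.testing.assert_allclose(np.abs(load).T @ coef, [2.0, 8.0, 4.0])

    def test_refit_importance_connectivity_backprojects_to_raw_features(
        self, tiny_cohort_module
    ):
        cohort, feats, _ = tiny_cohort_module
        name = "rest_fc"  # connectivity set
        grid = HyperGrid(alphas=(0.1, 1.0), l1_ratios=(0.5,))
        it = refit_importance(feats[name], cohort, "age", "connectivity",
                              grid, seed=0, n_components=10, model_name=name)
        assert len(it.importance) == feats[name].shape[1]

    def test_all_zero_coefficients_give_zero_importance(self, tiny_cohort_module):
        cohort, feats, _ = tiny_cohort_module
        name = "rest_fc"
        grid = HyperGrid.single(1e8, 1.0)  # everything shrunk away
        it = refit_importance(feats[name], cohort, "age", "connectivity",
                              grid, seed=0, n_components=10)
        np.testing.assert_array_equal(it.importance.to_numpy(), 0.0)


class TestStability:
    def test_identical_vectors_give_rho_one(self):
        v = np.arange(10.0)
        rhos = importance_stability([v] * 5)
        assert len(rhos) == 10
        np.testing.assert_allclose(rhos, 1.0)

    def test_reversed_vector_gives_rho_minus_one_on_its_pairs(self):
        v = np.arange(10.0)
        rhos = importance_stability([v, v, v, v, v[::-1]])
        assert sum(r == pytest.approx(-1.0) for r in rhos) == 4
        assert sum(r == pytest.approx(1.0) for r in rhos) == 6

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(4)
        vecs = [rng.standard_normal(30) for _ in range(5)]
        rhos = importance_stability(vecs)
        from scipy.stats import rankdata

        k = 0
        for i in range(5):
            for j in range(i + 1, 5):
                r = np.corrcoef(rankdata(vecs[i]), rankdata(vecs[j]))[0, 1]
                assert rhos[k] == pytest.approx(r, abs=1e-12)
                k += 1

    def test_constant_vector_yields_nan(self):
        v = np.arange(5.0)
        rhos = importance_stability([v, np.ones(5), v, v, v])
        assert np.isnan(rhos[0])
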
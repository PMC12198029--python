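"""Feature ranking, CV signature search, learners, grid."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import RepeatedStratifiedKFold

from pgtrange.modeling import (
    LEARNERS,
    RANKING_METHODS,
    LearnerParams,
    cv_signature_search,
    predict,
    rank_features,
    run_grid,
    train_learner,
)
from pgtrange.spectra import ValidationError

SMALL_PARAMS = LearnerParams(rf_trees=10, xgb_rounds=10)


def model_table(values: np.ndarray, target: np.ndarray, split="train", energy=162.0):
    n = len(target)
    cols = {f"f{j:02d}": values[:, j] for j in range(values.shape[1])}
    return pd.DataFrame(
        {
            "beam_energy": energy,
            "mode": "static",
            "dataset": "static",
            "cavity_mm": target,
            "split": split,
            **cols,
        },
        index=[f"s{i}" for i in range(n)],
    )


def planted_table(rng, n=200, noise_features=20, informative_noise=0.1):
    target = rng.choice([0.0, 5.0, 10.0, 20.0], n)
    values = rng.normal(size=(n, noise_features + 1))
    values[:, 0] = target + informative_noise * rng.normal(size=n)
    return model_table(values, target)


class TestRanking:
    @pytest.mark.parametrize("method", RANKING_METHODS)
    def test_planted_feature_ranked_first(self, method, rng):
        table = planted_table(rng)
        ranking = rank_features(table, method)
        assert ranking.features[0] == "f00"

    def test_mrmr_separates_duplicates_spearman_does_not(self, rng):
        target = rng.choice([0.0, 5.0, 10.0, 20.0], 150)
        values = rng.normal(size=(150, 5))
        values[:, 0] = target + 0.1 * rng.normal(size=150)
        values[:, 1] = values[:, 0]  # exact duplicate
        table = model_table(values, target)
        spearman = rank_features(table, "spearman").features
        mrmr = rank_features(table, "mrmr").features
        assert set(spearman[:2]) == {"f00", "f01"}
        assert abs(mrmr.index("f00") - mrmr.index("f01")) > 1

    def test_single_feature_trivially_first(self, rng):
        table = model_table(rng.normal(size=(20, 1)), rng.choice([0.0, 5.0], 20))
        for method in RANKING_METHODS:
            assert rank_features(table, method).features == ("f00",)

    def test_too_few_rows_rejected(self, rng):
        table = model_table(rng.normal(size=(5, 2)), np.zeros(5))
        with pytest.raises(ValidationError, match="10"):
            rank_features(table, "spearman")

    def test_ranking_is_permutation(self, rng):
        table = planted_table(rng, n=60, noise_features=6)
        for method in RANKING_METHODS:
            ranking = rank_features(table, method)
            assert sorted(ranking.features) == sorted(
                c for c in table.columns if c.startswith("f")
            )


class TestSignatureSearch:
    def test_noiseless_linear_chooses_one_feature(self, rng):
        target = rng.choice([0.0, 5.0, 10.0, 20.0], 36)
        values = rng.normal(size=(36, 4))
        values[:, 0] = 0.5 * target
        table = model_table(values, target)
        ranking = rank_features(table, "spearman")
        model = cv_signature_search(table, ranking, "linear", seed=1, params=SMALL_PARAMS)
        assert model.chosen_k == 1
        assert model.cv_rmse[0] == pytest.approx(0.0, abs=1e-9)

    def test_cv_rmse_matches_handrolled_oracle(self, rng):
        """Independent CV loop (own OLS fit, shared folds) reproduces the
        per-size RMSE of the search for the linear learner."""
        target = rng.choice([0.0, 5.0, 10.0], 30)
        values = rng.normal(size=(30, 3))
        values[:, 0] = target + rng.normal(size=30)
        table = model_table(values, target)
        ranking = rank_features(table, "spearman")
        model = cv_signature_search(
            table, ranking, "linear", seed=3, params=SMALL_PARAMS, max_size=2
        )
        y = target
        strata = pd.factorize(y)[0]
        cv = RepeatedStratifiedKFold(n_splits=3, n_repeats=3, random_state=3)
        folds = list(cv.split(np.zeros_like(strata), strata))
        for k in (1, 2):
            cols = list(ranking.features[:k])
            fold_rmse = []
            for tr, va in folds:
                x_tr = np.column_stack([table[cols].to_numpy()[tr], np.ones(len(tr))])
                beta = np.linalg.lstsq(x_tr, y[tr], rcond=None)[0]
                x_va = np.column_stack([table[cols].to_numpy()[va], np.ones(len(va))])
                fold_rmse.append(np.sqrt(np.mean((x_va @ beta - y[va]) ** 2)))
            assert model.cv_rmse[k - 1] == pytest.approx(np.mean(fold_rmse), rel=1e-9)

    def test_same_seed_reproduces_search(self, rng):
        table = planted_table(rng, n=45, noise_features=4)
        ranking = rank_features(table, "lasso")
        a = cv_signature_search(table, ranking, "random_forest", seed=9, params=SMALL_PARAMS)
        b = cv_signature_search(table, ranking, "random_forest", seed=9, params=SMALL_PARAMS)
        assert a.signature == b.signature
        np.testing.assert_array_equal(a.cv_rmse, b.cv_rmse)


class TestLearners:
    def test_linear_recovers_exact_coefficients(self):
        x = np.arange(10.0)
        table = model_table(x[:, None], 2.0 * x + 1.0)
        model = train_learner(table, ("f00",), "linear")
        coef, intercept = model.state
        assert coef[0] == pytest.approx(2.0, abs=1e-9)
        assert intercept == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("learner", LEARNERS)
    def test_constant_target_predicted(self, learner, rng):
        table = model_table(rng.normal(size=(20, 2)), np.full(20, 7.0))
        model = train_learner(table, ("f00", "f01"), learner, params=SMALL_PARAMS)
        preds = model.predict(table)
        tol = 0 if learner in ("random_forest", "gradient_boosted_trees") else 1e-6
        np.testing.assert_allclose(preds, 7.0, atol=max(tol, 1e-12))

    @pytest.mark.parametrize("learner", ["random_forest", "gradient_boosted_trees"])
    def test_tree_train_rmse_below_cv_rmse(self, learner, rng):
        target = rng.choice([0.0, 5.0, 10.0, 20.0], 36)
        values = rng.normal(size=(36, 3))
        values[:, 0] = target + 2.0 * rng.normal(size=36)
        table = model_table(values, target)
        ranking = rank_features(table, "spearman")
        model = cv_signature_search(table, ranking, learner, seed=2, params=SMALL_PARAMS)
        train_preds = predict(model, table)
        train_rmse = np.sqrt(np.mean((train_preds - target) ** 2))
        assert train_rmse <= model.best_cv_rmse

    def test_rank_deficient_design_warns(self):
        x = np.ones((12, 2))  # two identical constant columns
        table = model_table(x, np.arange(12.0))
        with pytest.warns(UserWarning, match="minimum-norm"):
            train_learner(table, ("f00", "f01"), "linear")


class TestPredict:
    def test_exact_on_noiseless_training_rows(self):
        x = np.linspace(0, 10, 12)
        table = model_table(x[:, None], 3.0 * x - 2.0)
        model = train_learner(table, ("f00",), "linear")
        np.testing.assert_allclose(model.predict(table), 3.0 * x - 2.0, atol=1e-9)

    def test_row_permutation_permutes_predictions(self, rng):
        table = planted_table(rng, n=30, noise_features=2)
        model = train_learner(table, ("f00",), "linear")
        perm = rng.permutation(len(table))
        np.testing.assert_allclose(
            model.predict(table.iloc[perm]), model.predict(table)[perm]
        )

    def test_missing_signature_column_named(self, rng):
        table = planted_table(rng, n=30, noise_features=2)
        model = train_learner(table, ("f00",), "linear")
        with pytest.raises(KeyError, match="f00"):
            model.predict(table.drop(columns=["f00"]))

    def test_refit_oracle_agrees(self, rng):
        """Refitting the same learner outside the pipeline reproduces the
        pipeline's predictions."""
        from sklearn.ensemble import RandomForestRegressor

        table = planted_table(rng, n=40, noise_features=2)
        model = train_learner(table, ("f00", "f01"), "random_forest", seed=5, params=SMALL_PARAMS)
        oracle = RandomForestRegressor(n_estimators=10, random_state=5, n_jobs=1)
        oracle.fit(table[["f00", "f01"]].to_numpy(), table["cavity_mm"].to_numpy())
        np.testing.assert_allclose(
            model.predict(table), oracle.predict(table[["f00", "f01"]].to_numpy())
        )


def grid_tables(rng, n=36):
    target = np.tile([0.0, 5.0, 10.0, 20.0], n // 4)
    tables = {}
    for set_name in ("time", "ert", "energy", "image", "combined"):
        values = rng.normal(size=(n, 4))
        values[:, 0] = target + 0.5 * rng.normal(size=n)
        t = model_table(values, target)
        t.columns = [
            c if not c.startswith("f") else f"{set_name}:all:all:{c}" for c in t.columns
        ]
        tables[set_name] = t
    return tables


class TestGrid:
    def test_subset_iii_pools_both_energies(self, rng):
        a = planted_table(rng, n=24, noise_features=2)
        b = planted_table(rng, n=24, noise_features=2)
        b["beam_energy"] = 225.0
        pooled = pd.concat([a, pd.DataFrame(b.values, columns=b.columns, index=[f"t{i}" for i in range(24)])])
        assert len(pooled) == len(a) + len(b)

    def test_grid_rerun_same_seed_identical_best(self, rng):
        tables = grid_tables(rng)
        a = run_grid(tables, seed=4, params=SMALL_PARAMS, max_size=2)
        b = run_grid(tables, seed=4, params=SMALL_PARAMS, max_size=2)
        assert a.best.config_name == b.best.config_name
        assert a.best.to_bytes() == b.best.to_bytes()
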
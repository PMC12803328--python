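"""Preprocessing and tabular model behaviour on the feature table."""

import numpy as np
import pandas as pd
import pytest

from lairelease.errors import ConfigError, DegenerateTrainingError
from lairelease.profiles import resample_profile, uniform_grid
from lairelease.records import FEATURE_COLUMNS
from lairelease.synthetic import generate_formulations
from lairelease.records import records_to_frame
from lairelease.tabular import (
    FeatureMatrix,
    ModelSpec,
    encode_and_standardize,
    fit_predict_classification,
    fit_predict_profile_with_time,
    fit_predict_regression,
    sample_spec,
    validate_hyperparameters,
)


def _frame(n=30, seed=0):
    return records_to_frame(generate_formulations(n, seed=seed))


def _toy_matrix(X):
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(
        ids=[str(i) for i in range(len(X))],
        X=X,
        columns=[f"x{j}" for j in range(X.shape[1])],
    )


class TestEncodeAndStandardize:
    def test_zscore_of_arithmetic_sequence(self):
        df = _frame(3)
        df["drug_mw"] = [1.0, 2.0, 3.0]
        fm, _ = encode_and_standardize(df)
        col = fm.columns.index("drug_mw")
        np.testing.assert_allclose(fm.X[:, col], [-1.2247, 0, 1.2247], atol=1e-4)

    def test_transform_reuses_training_stats(self):
        train = _frame(3)
        train["drug_mw"] = [1.0, 2.0, 3.0]
        fm, stats = encode_and_standardize(train)
        test = train.iloc[[1]]
        fm_test, _ = encode_and_standardize(test, stats)
        col = fm.columns.index("drug_mw")
        assert fm_test.X[0, col] == pytest.approx(0.0)

    def test_constant_column_maps_to_zeros(self):
        df = _frame(5)
        df["la_ga_ratio"] = 1.0
        fm, _ = encode_and_standardize(df)
        col = fm.columns.index("la_ga_ratio")
        assert np.all(fm.X[:, col] == 0.0)
        assert np.all(np.isfinite(fm.X))

    def test_unseen_category_maps_to_zero_vector(self):
        train = _frame(10)
        fm, stats = encode_and_standardize(train)
        test = train.iloc[[0]].copy()
        test["formulation_method"] = "electro-spraying"
        with pytest.warns(UserWarning, match="unseen"):
            fm_test, _ = encode_and_standardize(test, stats)
        onehot_cols = [i for i, c in enumerate(fm.columns) if c.startswith("formulation_method=")]
        raw = fm_test.X[0, onehot_cols]
        # one-hot block is the standardized image of the all-zero vector
        means = stats.means[[fm.columns[i] for i in onehot_cols]].to_numpy()
        sds = stats.sds[[fm.columns[i] for i in onehot_cols]].to_numpy()
        np.testing.assert_allclose(raw, (0 - means) / np.where(sds > 0, sds, 1.0))

    def test_median_imputation_of_missing_values(self):
        df = _frame(5)
        df.loc[2, "drug_tpsa"] = np.nan
        fm, stats = encode_and_standardize(df)
        assert np.all(np.isfinite(fm.X))

    def test_standardization_independent_of_test_rows(self):
        train = _frame(20, seed=1)
        _, stats_a = encode_and_standardize(train)
        _, stats_b = encode_and_standardize(train)
        pd.testing.assert_series_equal(stats_a.means, stats_b.means)


class TestSearchSpaces:
    @pytest.mark.parametrize("family", ["logistic_linear", "random_forest", "gbdt"])
    def test_sampled_specs_validate(self, family, rng):
        task = "classification" if family == "logistic_linear" else "regression"
        for _ in range(20):
            spec = sample_spec(family, task, rng)
            validate_hyperparameters(family, spec.hyperparameters)

    def test_out_of_space_values_rejected(self):
        with pytest.raises(ConfigError):
            ModelSpec("gbdt", "regression", {"max_depth": 50})
        with pytest.raises(ConfigError):
            ModelSpec("random_forest", "regression", {"n_estimators": 10})
        with pytest.raises(ConfigError):
            ModelSpec("gbdt", "regression", {"unknown_knob": 1})


class TestRegression:
    def test_tree_overfits_seen_data(self):
        fm, _ = encode_and_standardize(_frame(20))
        y = np.linspace(0, 1, 20)
        spec = ModelSpec("gbdt", "regression", {"max_depth": 6, "n_estimators": 200})
        pred = fit_predict_regression(fm, y, fm, spec)
        assert np.sqrt(np.mean((pred - y) ** 2)) < 0.02

    def test_constant_target_for_trees(self):
        fm, _ = encode_and_standardize(_frame(15))
        y = np.full(15, 0.3)
        spec = ModelSpec("random_forest", "regression", {"n_estimators": 50})
        pred = fit_predict_regression(fm, y, fm, spec)
        np.testing.assert_allclose(pred, 0.3, atol=1e-9)

    def test_linear_family_matches_ols_oracle(self, rng):
        X = rng.normal(size=(40, 4))
        beta = np.array([1.0, -2.0, 0.5, 3.0])
        y = X @ beta + 0.7
        # oracle: normal equations solved independently
        Xa = np.hstack([X, np.ones((40, 1))])
        coef = np.linalg.lstsq(Xa, y, rcond=None)[0]
        fm = _toy_matrix(X)
        spec = ModelSpec("linear_regression", "regression")
        pred = fit_predict_regression(fm, y, fm, spec)
        np.testing.assert_allclose(pred, Xa @ coef, atol=1e-8)
        assert np.sqrt(np.mean((pred - y) ** 2)) < 1e-6

    def test_task_mismatch_rejected(self):
        fm = _toy_matrix(np.zeros((4, 2)))
        spec = ModelSpec("gbdt", "classification", {})
        with pytest.raises(ConfigError):
            fit_predict_regression(fm, np.zeros(4), fm, spec)


class TestClassification:
    def test_separable_toy_perfect_training_accuracy(self, rng):
        X = np.vstack([rng.normal(-3, 0.3, (20, 2)), rng.normal(3, 0.3, (20, 2))])
        y = np.array([0] * 20 + [1] * 20)
        fm = _toy_matrix(X)
        for family in ("logistic_linear", "random_forest", "gbdt"):
            spec = ModelSpec(family, "classification", {})
            pred, scores = fit_predict_classification(fm, y, fm, spec)
            assert np.array_equal(pred, y)
            assert np.all((scores >= 0) & (scores <= 1))

    def test_threshold_rule_learnable_by_trees(self, rng):
        X = rng.normal(size=(200, 5))
        y = (X[:, 2] > np.median(X[:, 2])).astype(int)
        fm_tr, fm_te = _toy_matrix(X[:150]), _toy_matrix(X[150:])
        spec = ModelSpec("gbdt", "classification", {"max_depth": 3, "n_estimators": 100})
        pred, _ = fit_predict_classification(fm_tr, y[:150], fm_te, spec)
        assert np.mean(pred == y[150:]) > 0.9

    def test_label_score_consistency(self, rng):
        X = rng.normal(size=(60, 3))
        y = (X[:, 0] > 0).astype(int)
        fm = _toy_matrix(X)
        spec = ModelSpec("random_forest", "classification", {})
        pred, scores = fit_predict_classification(fm, y, fm, spec)
        np.testing.assert_array_equal(pred, (scores > 0.5).astype(int))

    def test_single_class_training_rejected(self):
        fm = _toy_matrix(np.zeros((5, 2)))
        spec = ModelSpec("gbdt", "classification", {})
        with pytest.raises(DegenerateTrainingError):
            fit_predict_classification(fm, np.ones(5), fm, spec)


class TestMonotoneTransformInvariance:
    def test_tree_predictions_invariant_to_monotone_feature_transform(self, rng):
        """Squashing a feature through exp leaves tree predictions unchanged."""
        X = rng.normal(size=(60, 3))
        y = X[:, 0] ** 2 + X[:, 1]
        spec = ModelSpec("random_forest", "regression", {"n_estimators": 60, "bootstrap": False})
        base = fit_predict_regression(_toy_matrix(X[:40]), y[:40], _toy_matrix(X[40:]), spec)
        Xt = X.copy()
        Xt[:, 1] = np.exp(Xt[:, 1])  # strictly monotone transform
        yt = X[:, 0] ** 2 + X[:, 1]  # target unchanged
        trans = fit_predict_regression(_toy_matrix(Xt[:40]), yt[:40], _toy_matrix(Xt[40:]), spec)
        np.testing.assert_allclose(base, trans, atol=1e-9)


class TestProfileWithTime:
    def _setup(self, n=25, T=21, seed=4):
        from lairelease.synthetic import generate_dataset

        ds = generate_dataset(n, seed=seed)
        fm, _ = encode_and_standardize(ds.feature_frame())
        R = np.vstack([resample_profile(p, T, "max").values for p in ds.profiles])
        return fm, R, uniform_grid(T)

    def test_no_time_ablation_gives_flat_profiles(self):
        fm, R, grid = self._setup()
        spec = ModelSpec("gbdt", "regression", {"max_depth": 4, "n_estimators": 60})
        P = fit_predict_profile_with_time(fm, R, fm, grid, spec, include_time=False)
        assert np.ptp(P, axis=1).max() < 1e-9  # constant across the grid

    def test_train_equals_test_near_zero_error(self):
        fm, R, grid = self._setup(n=1)
        spec = ModelSpec("gbdt", "regression", {"max_depth": 6, "n_estimators": 300, "learning_rate": 0.3})
        P = fit_predict_profile_with_time(fm, R, fm, grid, spec, include_time=True)
        assert np.sqrt(np.mean((P - R) ** 2)) < 0.02

    def test_monophasic_data_learnable_from_time_alone(self):
        from lairelease.synthetic import SyntheticConfig, generate_dataset

        cfg = SyntheticConfig(class0_templates={"monophasic": 1.0})
        ds = generate_dataset(30, seed=6, mixture=(1.0, 0.0), config=cfg)
        assert (ds.truth["template"] == "monophasic").all()
        fm, _ = encode_and_standardize(ds.feature_frame())
        grid = uniform_grid(31)
        R = np.vstack([resample_profile(p, 31, "max").values for p in ds.profiles])
        spec = ModelSpec("gbdt", "regression", {"max_depth": 4, "n_estimators": 150})
        P = fit_predict_profile_with_time(fm, R, fm, grid, spec, include_time=True)
        assert np.sqrt(np.mean((P - R) ** 2)) < 0.1

    def test_grid_mismatch_rejected(self):
        fm, R, grid = self._setup()
        spec = ModelSpec("gbdt", "regression", {})
        with pytest.raises(ConfigError):
            fit_predict_profile_with_time(fm, R, fm, grid[:-1], spec)
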
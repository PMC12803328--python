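"""Tabular models on the 11-descriptor feature table.

Covers the early-release regressors (ordinary linear regression, random
forest, gradient-boosted trees — the latter labelled "XGB" in reports),
the release-type classifiers (logistic regression, RF, XGB) and the
time-as-input gradient-boosted baseline that predicts a complete profile
by treating the normalized time point as an extra feature.

Preprocessing one-hot encodes the formulation method and z-scores the
continuous descriptors using training-fold statistics only, so nested
cross-validation never leaks test information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression
from xgboost import XGBClassifier, XGBRegressor

from .errors import ConfigError, DegenerateTrainingError
from .records import (
    CATEGORICAL_COLUMNS,
    CONTINUOUS_COLUMNS,
    FEATURE_COLUMNS,
)

FAMILIES = ("linear_regression", "logistic_linear", "random_forest", "gbdt")

#: Hyperparameter search spaces.  Each entry is
#: ("int"|"float"|"logfloat", low, high) or ("cat", (choices...)).
SEARCH_SPACES: dict[str, dict[str, tuple]] = {
    "logistic_linear": {
        "C": ("logfloat", 1e-4, 1e4),
        "penalty": ("cat", ("l1", "l2")),
        "solver": ("cat", ("liblinear",)),
        "max_iter": ("int", 200, 1000),
        "class_weight": ("cat", (None, "balanced")),
        "tol": ("logfloat", 1e-6, 1e-3),
    },
    "random_forest": {
        "n_estimators": ("int", 50, 300),
        "max_depth": ("int", 3, 20),
        "min_samples_split": ("int", 2, 20),
        "min_samples_leaf": ("int", 1, 10),
        "max_features": ("cat", ("sqrt", "log2")),
        "bootstrap": ("cat", (True, False)),
    },
    "gbdt": {
        "max_depth": ("int", 3, 20),
        "learning_rate": ("float", 0.01, 0.3),
        "n_estimators": ("int", 50, 300),
        "colsample_bytree": ("float", 0.5, 1.0),
        "gamma": ("float", 0.0, 5.0),
        "reg_alpha": ("float", 0.0, 1.0),
        "reg_lambda": ("float", 0.0, 1.0),
    },
    "linear_regression": {},
}

#: Report label used for the gradient-boosted family.
FAMILY_LABELS = {
    "linear_regression": "LinR",
    "logistic_linear": "LR",
    "random_forest": "RF",
    "gbdt": "XGB",
}


@dataclass(frozen=True)
class ModelSpec:
    """A model family, task and a hyperparameter assignment.

    Hyperparameters must validate against the family's encoded search
    space; missing ones fall back to library defaults.
    """

    family: str
    task: str  # "regression" or "classification"
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown family {self.family!r}")
        if self.task not in ("regression", "classification"):
            raise ConfigError(f"unknown task {self.task!r}")
        if self.family == "linear_regression" and self.task != "regression":
            raise ConfigError("linear_regression only supports regression")
        if self.family == "logistic_linear" and self.task != "classification":
            raise ConfigError("logistic_linear only supports classification")
        validate_hyperparameters(self.family, self.hyperparameters)


def validate_hyperparameters(family: str, hp: dict) -> None:
    """Check names and ranges against the family's search space."""
    space = SEARCH_SPACES[family]
    for name, value in hp.items():
        if name not in space:
            raise ConfigError(f"{family}: unknown hyperparameter {name!r}")
        kind, *rest = space[name]
        if kind == "cat":
            if value not in rest[0]:
                raise ConfigError(
                    f"{family}.{name}: {value!r} not in {rest[0]}"
                )
        else:
            lo, hi = rest
            if not (lo <= value <= hi):
                raise ConfigError(
                    f"{family}.{name}: {value} outside [{lo}, {hi}]"
                )
            if kind == "int" and int(value) != value:
                raise ConfigError(f"{family}.{name}: {value} is not integral")


def sample_spec(family: str, task: str, rng: np.random.Generator) -> ModelSpec:
    """Draw one hyperparameter assignment uniformly from the search space
    (log-uniform for scale parameters)."""
    hp = {}
    for name, spec in SEARCH_SPACES[family].items():
        kind, *rest = spec
        if kind == "cat":
            hp[name] = rest[0][int(rng.integers(len(rest[0])))]
        elif kind == "int":
            hp[name] = int(rng.integers(rest[0], rest[1] + 1))
        elif kind == "float":
            hp[name] = float(rng.uniform(rest[0], rest[1]))
        else:  # logfloat
            hp[name] = float(np.exp(rng.uniform(np.log(rest[0]), np.log(rest[1]))))
    return ModelSpec(family=family, task=task, hyperparameters=hp)


@dataclass(frozen=True)
class StandardizationStats:
    """Training-fold preprocessing state, reusable on held-out data."""

    categories: dict  # categorical column -> ordered category list
    medians: pd.Series  # imputation values for continuous columns
    means: pd.Series  # z-score means (over encoded columns)
    sds: pd.Series  # z-score sds, zero-variance columns flagged by sd == 0


@dataclass(frozen=True)
class FeatureMatrix:
    """Standardized numeric design matrix with aligned ids and columns."""

    ids: list
    X: np.ndarray
    columns: list

    def __post_init__(self):
        if self.X.shape != (len(self.ids), len(self.columns)):
            raise ConfigError(
                f"feature matrix shape {self.X.shape} does not match "
                f"{len(self.ids)} ids x {len(self.columns)} columns"
            )


def encode_and_standardize(
    frame: pd.DataFrame, fit_stats: StandardizationStats | None = None
) -> tuple[FeatureMatrix, StandardizationStats]:
    """One-hot encode the formulation method and z-score everything.

    When ``fit_stats`` is given they are applied verbatim (never re-fit),
    which is how held-out folds are transformed.  Missing continuous
    values are imputed with the training-fold median; unseen categories
    map to the all-zeros vector with a warning; zero-variance columns
    standardize to zeros rather than NaN.
    """
    missing = [c for c in FEATURE_COLUMNS if c not in frame.columns]
    if missing:
        raise ConfigError(f"feature frame lacks columns: {missing}")
    ids = [str(i) for i in frame["formulation_id"]] if "formulation_id" in frame else [
        str(i) for i in frame.index
    ]

    if fit_stats is None:
        categories = {
            c: sorted(frame[c].dropna().astype(str).unique())
            for c in CATEGORICAL_COLUMNS
        }
        medians = frame[CONTINUOUS_COLUMNS].median()
    else:
        categories = fit_stats.categories
        medians = fit_stats.medians

    blocks, columns = [], []
    for c in CATEGORICAL_COLUMNS:
        cats = categories[c]
        observed = frame[c].astype(str)
        unseen = set(observed.unique()) - set(cats)
        if unseen:
            warnings.warn(
                f"unseen {c} categories {sorted(unseen)} mapped to zero vector",
                stacklevel=2,
            )
        onehot = np.column_stack(
            [(observed == cat).to_numpy(dtype=float) for cat in cats]
        )
        blocks.append(onehot)
        columns.extend(f"{c}={cat}" for cat in cats)
    cont = frame[CONTINUOUS_COLUMNS].apply(pd.to_numeric, errors="coerce")
    cont = cont.fillna(medians)
    blocks.append(cont.to_numpy(dtype=float))
    columns.extend(CONTINUOUS_COLUMNS)
    raw = np.hstack(blocks)

    if fit_stats is None:
        means = pd.Series(raw.mean(axis=0), index=columns)
        sds = pd.Series(raw.std(axis=0, ddof=0), index=columns)
        fit_stats = StandardizationStats(categories, medians, means, sds)
    means = fit_stats.means.reindex(columns).to_numpy()
    sds = fit_stats.sds.reindex(columns).to_numpy()
    safe_sds = np.where(sds > 0, sds, 1.0)
    X = (raw - means) / safe_sds
    X[:, sds == 0] = 0.0  # zero-variance guard
    return FeatureMatrix(ids=ids, X=X, columns=columns), fit_stats


def make_model(spec: ModelSpec, seed: int = 42):
    """Instantiate the sklearn/xgboost estimator for a model spec."""
    hp = dict(spec.hyperparameters)
    if spec.family == "linear_regression":
        return LinearRegression()
    if spec.family == "logistic_linear":
        hp.setdefault("solver", "liblinear")
        return LogisticRegression(random_state=seed, **hp)
    if spec.family == "random_forest":
        cls = (
            RandomForestRegressor
            if spec.task == "regression"
            else RandomForestClassifier
        )
        return cls(random_state=seed, n_jobs=1, **hp)
    cls = XGBRegressor if spec.task == "regression" else XGBClassifier
    return cls(
        random_state=seed,
        n_jobs=1,
        verbosity=0,
        tree_method="hist",
        **hp,
    )


def fit_predict_regression(
    train: FeatureMatrix,
    targets: np.ndarray,
    test: FeatureMatrix,
    spec: ModelSpec,
    seed: int = 42,
) -> np.ndarray:
    """Fit a regression spec on the training fold and predict the test fold."""
    if spec.task != "regression":
        raise ConfigError(f"spec task {spec.task!r} is not regression")
    model = make_model(spec, seed)
    model.fit(train.X, np.asarray(targets, dtype=float))
    return np.asarray(model.predict(test.X), dtype=float)


def fit_predict_classification(
    train: FeatureMatrix,
    labels: np.ndarray,
    test: FeatureMatrix,
    spec: ModelSpec,
    seed: int = 42,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit a classification spec; return predicted labels and class-1 scores."""
    if spec.task != "classification":
        raise ConfigError(f"spec task {spec.task!r} is not classification")
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("training labels contain a single class")
    model = make_model(spec, seed)
    model.fit(train.X, y)
    scores = np.asarray(model.predict_proba(test.X)[:, 1], dtype=float)
    return (scores > 0.5).astype(int), scores


def fit_profile_with_time(
    train: FeatureMatrix,
    train_profiles: np.ndarray,
    grid: np.ndarray,
    spec: ModelSpec,
    include_time: bool = True,
    seed: int = 42,
):
    """Fit the time-as-input GBDT profile baseline ("XGB-Time").

    Each training formulation contributes one row per grid point,
    ``(features ⊕ t_norm) -> release value``.  With ``include_time=False``
    (the ablation) the t_norm column is dropped, so every grid point of a
    formulation presents identical inputs and the fitted model can only
    produce a flat profile.
    """
    R = np.asarray(train_profiles, dtype=float)
    n, T = R.shape
    if len(grid) != T:
        raise ConfigError(f"grid length {len(grid)} != profile width {T}")
    Xrep = np.repeat(train.X, T, axis=0)
    if include_time:
        tcol = np.tile(np.asarray(grid, dtype=float), n)[:, None]
        Xrep = np.hstack([Xrep, tcol])
    model = make_model(spec, seed)
    model.fit(Xrep, R.ravel())
    return model


def predict_profile_with_time(
    model, test: FeatureMatrix, grid: np.ndarray, include_time: bool = True
) -> np.ndarray:
    """Evaluate a time-as-input baseline at every grid point per test row."""
    T = len(grid)
    Xrep = np.repeat(test.X, T, axis=0)
    if include_time:
        tcol = np.tile(np.asarray(grid, dtype=float), len(test.ids))[:, None]
        Xrep = np.hstack([Xrep, tcol])
    pred = np.asarray(model.predict(Xrep), dtype=float)
    return pred.reshape(len(test.ids), T)


def fit_predict_profile_with_time(
    train: FeatureMatrix,
    train_profiles: np.ndarray,
    test: FeatureMatrix,
    grid: np.ndarray,
    spec: ModelSpec,
    include_time: bool = True,
    seed: int = 42,
) -> np.ndarray:
    """Convenience wrapper: fit the baseline and predict test profiles."""
    model = fit_profile_with_time(
        train, train_profiles, grid, spec, include_time, seed
    )
    return predict_profile_with_time(model, test, grid, include_time)
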
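"""Shapley attribution of tabular model predictions to material descriptors.

Attributions satisfy local accuracy: per sample, the base value plus the
per-feature Shapley values equals the model output (raw prediction for
regressors, log-odds margin for logistic and gradient-boosted
classifiers, class-1 probability for random-forest classifiers).

Explainers are exact for every supported family: closed-form values for
linear and logistic models, the gradient-boosted trees' built-in
tree-path contributions, and a path-dependent TreeSHAP recursion for
random forests.  Rankings, top-k attribution shares and directional
effect summaries condense the per-sample values into the tabular
summaries used to compare material characteristics.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xgboost
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LinearRegression, LogisticRegression

from ._treeshap import TreeArrays, ensemble_shap
from .errors import UnsupportedExplainerError
from .tabular import FeatureMatrix


class AttributionReport:
    """Per-sample per-feature Shapley values plus the aligned inputs.

    Attributes
    ----------
    values : (n, d) array of Shapley values.
    base_values : (n,) array; ``base_values + values.sum(1)`` equals the
        model output on the explained scale.
    X : the explained samples, aligned with ``values``.
    model_output : the model's raw output per sample (for the local
        accuracy check).
    """

    def __init__(self, feature_names, values, base_values, X, model_output, ids=None):
        self.feature_names = list(feature_names)
        self.values = np.asarray(values, dtype=float)
        self.base_values = np.asarray(base_values, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.model_output = np.asarray(model_output, dtype=float)
        self.ids = list(ids) if ids is not None else None

    @property
    def mean_abs(self) -> np.ndarray:
        return np.abs(self.values).mean(axis=0)

    def local_accuracy_residuals(self) -> np.ndarray:
        """Per-sample |base + sum(values) - model_output|."""
        return np.abs(self.base_values + self.values.sum(axis=1) - self.model_output)

    @classmethod
    def concatenate(cls, reports) -> "AttributionReport":
        """Stack per-fold reports (e.g. one per outer test fold)."""
        reports = list(reports)
        return cls(
            reports[0].feature_names,
            np.vstack([r.values for r in reports]),
            np.concatenate([r.base_values for r in reports]),
            np.vstack([r.X for r in reports]),
            np.concatenate([r.model_output for r in reports]),
            ids=sum([r.ids or [] for r in reports], []) or None,
        )


def _linear_attributions(model, X, background):
    mu = background.mean(axis=0)
    if isinstance(model, LogisticRegression):
        w = model.coef_[0]
        b = float(model.intercept_[0])
        output = model.decision_function(X)
    else:
        w = np.asarray(model.coef_, dtype=float)
        b = float(model.intercept_)
        output = model.predict(X)
    values = (X - mu) * w
    base = np.full(len(X), float(w @ mu + b))
    return values, base, np.asarray(output, dtype=float)


def _xgb_attributions(model, X):
    booster = model.get_booster()
    contribs = booster.predict(xgboost.DMatrix(X), pred_contribs=True)
    values, base = contribs[:, :-1], contribs[:, -1]
    output = booster.predict(xgboost.DMatrix(X), output_margin=True)
    return values, base, np.asarray(output, dtype=float)


def _forest_attributions(model, X):
    class1 = isinstance(model, RandomForestClassifier)
    trees = [TreeArrays.from_sklearn(est, class1=class1) for est in model.estimators_]
    values, base = ensemble_shap(trees, X, average=True)
    output = (
        model.predict_proba(X)[:, 1] if class1 else model.predict(X)
    )
    return values, np.full(len(X), base), np.asarray(output, dtype=float)


def compute_attributions(
    model,
    X_test,
    feature_names=None,
    background: np.ndarray | None = None,
    ids=None,
) -> AttributionReport:
    """Exact Shapley attributions of a fitted tabular model on test rows.

    ``background`` (the reference data, normally the training fold) is
    only needed for linear models, whose attributions are
    ``w_j (x_j - mean(background_j))``; tree explainers carry their own
    cover-based reference.
    """
    if isinstance(X_test, FeatureMatrix):
        ids = ids or X_test.ids
        feature_names = feature_names or X_test.columns
        X = X_test.X
    else:
        X = np.asarray(X_test, dtype=float)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    if isinstance(model, (LinearRegression, LogisticRegression)):
        bg = X if background is None else np.asarray(background, dtype=float)
        values, base, output = _linear_attributions(model, X, bg)
    elif isinstance(model, (xgboost.XGBRegressor, xgboost.XGBClassifier)):
        values, base, output = _xgb_attributions(model, X)
    elif isinstance(model, (RandomForestRegressor, RandomForestClassifier)):
        values, base, output = _forest_attributions(model, X)
    else:
        raise UnsupportedExplainerError(
            f"no exact explainer for {type(model).__name__}"
        )
    return AttributionReport(feature_names, values, base, X, output, ids=ids)


def rank_features(report: AttributionReport) -> pd.DataFrame:
    """Features ordered by descending mean |attribution|, with shares.

    Ties break alphabetically.  ``share`` is each feature's fraction of
    the total mean |attribution|; with all-zero attributions the shares
    are undefined and the frame is flagged degenerate
    (``df.attrs["degenerate"]``).
    """
    mean_abs = report.mean_abs
    df = pd.DataFrame({"feature": report.feature_names, "mean_abs": mean_abs})
    df = df.sort_values(
        ["mean_abs", "feature"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    total = df["mean_abs"].sum()
    df.attrs["degenerate"] = bool(total == 0)
    df["share"] = df["mean_abs"] / total if total > 0 else np.nan
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def top_k_share(report: AttributionReport, k: int) -> float:
    """Fraction of total mean |attribution| carried by the top k features."""
    ranked = rank_features(report)
    if ranked.attrs["degenerate"]:
        return float("nan")
    return float(ranked["share"].iloc[:k].sum())


NEUTRAL_BAND = 0.1


def directional_effect_summary(
    report: AttributionReport, features=None
) -> pd.DataFrame:
    """Per-feature direction of effect on the model output.

    The direction is the sign of the Spearman rank correlation between a
    feature's values and its attributions; |rho| below 0.1 (or undefined,
    e.g. a constant feature) reports "neutral".
    """
    names = list(features) if features is not None else report.feature_names
    # attributions at floating-point noise level carry no direction
    floor = 1e-9 * max(1.0, float(np.abs(report.model_output).max()))
    rows = []
    for name in names:
        j = report.feature_names.index(name)
        x, v = report.X[:, j], report.values[:, j]
        if np.std(x) == 0 or np.std(v) == 0 or np.abs(v).mean() < floor:
            rho = float("nan")
        else:
            rho = float(sps.spearmanr(x, v).statistic)
        if not np.isfinite(rho) or abs(rho) < NEUTRAL_BAND:
            direction = "neutral"
        else:
            direction = "increases" if rho > 0 else "decreases"
        rows.append({"feature": name, "spearman_rho": rho, "direction": direction})
    return pd.DataFrame(rows)


def attributions_over_folds(cv_report, feature_frame: pd.DataFrame) -> AttributionReport:
    """Concatenate per-outer-fold attributions from a nested-CV report.

    Each outer fold's fitted model explains its own test rows (transformed
    with that fold's training statistics), mirroring how the out-of-fold
    predictions were produced.  Requires ``run_nested_cv(...,
    store_models=True)``.
    """
    from .tabular import encode_and_standardize

    if not cv_report.models:
        raise UnsupportedExplainerError(
            "nested-CV report holds no fitted models; rerun with store_models=True"
        )
    reports = []
    for entry in cv_report.models:
        fm_test, _ = encode_and_standardize(
            feature_frame.iloc[entry["test_idx"]], entry["stats"]
        )
        reports.append(compute_attributions(entry["model"], fm_test))
    return AttributionReport.concatenate(reports)
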
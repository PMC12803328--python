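"""Nested cross-validation protocol and evaluation metrics.

The protocol is 10x2 nested CV: ten outer folds each hold out one test
fold; the nine training folds are split into two inner folds on which a
seeded random hyperparameter search (50 trials by default) selects the
best setting by mean inner-validation score (negated RMSE for regression
and profile tasks, F1 for classification).  The selected model is refit
on the full nine folds and scored on the held-out fold; feature
standardization is fit on the nine training folds only and applied to
the test fold.  Sequence models train for 250 epochs during inner-fold
tuning and 500 epochs for the outer refit.

Reported metrics: RMSE and Pearson correlation (pooled over out-of-fold
predictions) for regression; accuracy, AUROC, precision, recall and F1
for classification; per-profile RMSE broken down by the true profile's
AUC class for complete-profile prediction.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import (
    accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import ConfigError, LaiReleaseError, ShapeError, UndefinedCorrelationError
from .profiles import NormalizedProfile, assign_profile_type, compute_auc
from .seqmodel import (
    BATCH_CHOICES,
    DROPOUT_CHOICES,
    EPOCHS_INNER,
    EPOCHS_OUTER,
    HIDDEN_CHOICES,
    LAYER_CHOICES,
    LR_CHOICES,
    SequenceModelConfig,
    predict_release_profile,
    train_sequence_model,
)
from .tabular import (
    FeatureMatrix,
    ModelSpec,
    encode_and_standardize,
    fit_predict_profile_with_time,
    make_model,
    sample_spec,
)

DEFAULT_TRIALS = 50
N_OUTER = 10
N_INNER = 2

#: Families accepted by the profile task.
PROFILE_FAMILIES = ("gbdt_time", "gbdt_no_time", "sequence_lstm", "sequence_gru")
PROFILE_LABELS = {
    "gbdt_time": "XGB-Time",
    "gbdt_no_time": "XGB-NoTime",
    "sequence_lstm": "FC-NN-LSTM",
    "sequence_gru": "FC-NN-GRU",
}


# --------------------------------------------------------------------- folds
@dataclass(frozen=True)
class FoldPlan:
    """Outer test index sets and, per outer fold, the inner train/val pairs.

    All index arrays are absolute row indices.  Outer test sets partition
    the samples; inner indices are drawn from the outer-train rows only.
    """

    outer_test: list
    outer_train: list
    inner: list  # inner[k] = [(train_idx, val_idx), ...] with n_inner pairs
    seed: int


def make_nested_folds(
    n: int,
    task: str,
    seed: int,
    labels=None,
    n_outer: int = N_OUTER,
    n_inner: int = N_INNER,
) -> FoldPlan:
    """Build the nested fold plan, stratified by label when one is given.

    Outer folds have sizes ``floor(n/n_outer)`` or ``ceil(n/n_outer)``.
    For each outer fold the training rows are split into ``n_inner``
    folds; each inner fold serves once as the validation set.
    """
    if n < n_outer:
        raise ConfigError(f"need n >= {n_outer} samples, got {n}")
    idx = np.arange(n)
    stratify = labels is not None and task in ("classification", "profile")
    if stratify:
        y = np.asarray(labels)
        outer_cv = StratifiedKFold(n_splits=n_outer, shuffle=True, random_state=seed)
        outer_splits = list(outer_cv.split(idx, y))
    else:
        outer_cv = KFold(n_splits=n_outer, shuffle=True, random_state=seed)
        outer_splits = list(outer_cv.split(idx))
    outer_test, outer_train, inner = [], [], []
    for k, (tr, te) in enumerate(outer_splits):
        outer_test.append(idx[te])
        outer_train.append(idx[tr])
        inner_seed = (seed * 1009 + k) % (2**31 - 1)
        if stratify:
            inner_cv = StratifiedKFold(
                n_splits=n_inner, shuffle=True, random_state=inner_seed
            )
            pairs = [
                (idx[tr][itr], idx[tr][iva])
                for itr, iva in inner_cv.split(idx[tr], np.asarray(labels)[tr])
            ]
        else:
            inner_cv = KFold(n_splits=n_inner, shuffle=True, random_state=inner_seed)
            pairs = [
                (idx[tr][itr], idx[tr][iva]) for itr, iva in inner_cv.split(idx[tr])
            ]
        inner.append(pairs)
    return FoldPlan(outer_test=outer_test, outer_train=outer_train, inner=inner, seed=seed)


# ------------------------------------------------------------------- metrics
def rmse(y, y_hat) -> float:
    """Root mean squared error."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape or len(y) < 1:
        raise ShapeError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def pearson_correlation(y, y_hat) -> float:
    """Product-moment correlation between true and predicted values."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.shape != y_hat.shape or len(y) < 2:
        raise ShapeError("need two equally long vectors of length >= 2")
    if np.std(y) == 0 or np.std(y_hat) == 0:
        raise UndefinedCorrelationError("zero variance input")
    return float(sps.pearsonr(y, y_hat)[0])


def classification_metrics(labels, predicted, scores) -> dict:
    """Accuracy, AUROC, precision, recall and F1 with class 1 positive.

    With a single-class truth the AUROC is undefined and reported as NaN
    (with a warning); the other metrics are still returned.
    """
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predicted, dtype=int)
    s = np.asarray(scores, dtype=float)
    out = {
        "accuracy": float(accuracy_score(y, p)),
        "precision": float(precision_score(y, p, zero_division=0)),
        "recall": float(recall_score(y, p, zero_division=0)),
        "f1": float(f1_score(y, p, zero_division=0)),
    }
    if len(np.unique(y)) < 2:
        warnings.warn("single-class truth: AUROC undefined", stacklevel=2)
        out["auroc"] = float("nan")
    else:
        out["auroc"] = float(roc_auc_score(y, s))
    return out


DEFAULT_AUC_BINS = (0.0, 0.3, 0.4, 0.5, 0.6, 0.7, 1.1)


def rmse_by_auc_group(
    true_profiles: np.ndarray,
    predicted_profiles: np.ndarray,
    grid: np.ndarray,
    bins=DEFAULT_AUC_BINS,
) -> pd.DataFrame:
    """Per-profile RMSE grouped by the true profile's AUC.

    Returns one row per binary class (AUC <= 0.5 / > 0.5), one per fine
    AUC bin, and an overall row, each with n, mean and sd of the
    per-profile RMSE over the grid points.  Empty groups are omitted with
    a warning.
    """
    R = np.asarray(true_profiles, dtype=float)
    P = np.asarray(predicted_profiles, dtype=float)
    if R.shape != P.shape:
        raise ShapeError(f"profile shapes differ: {R.shape} vs {P.shape}")
    grid = np.asarray(grid, dtype=float)
    aucs = np.array(
        [compute_auc(NormalizedProfile("g", grid, row)) for row in R]
    )
    per_profile = np.sqrt(np.mean((R - P) ** 2, axis=1))
    rows = []

    def add_group(name, mask):
        if not mask.any():
            warnings.warn(f"empty AUC group {name!r} omitted", stacklevel=3)
            return
        rows.append(
            {
                "group": name,
                "n": int(mask.sum()),
                "rmse_mean": float(per_profile[mask].mean()),
                "rmse_sd": float(per_profile[mask].std(ddof=0)),
            }
        )

    add_group("auc<=0.5", aucs <= 0.5)
    add_group("auc>0.5", aucs > 0.5)
    for lo, hi in zip(bins[:-1], bins[1:]):
        add_group(f"auc[{lo:g},{hi:g})", (aucs >= lo) & (aucs < hi))
    add_group("overall", np.ones(len(aucs), dtype=bool))
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- tuning
def _family_stream(seed: int, fold: int, family: str) -> np.random.Generator:
    """Independent, reproducible RNG per (seed, fold, family)."""
    tag = zlib.crc32(family.encode()) % (2**16)
    return np.random.default_rng(np.random.SeedSequence([seed % (2**31 - 1), fold, tag]))


def _sample_sequence_config(
    cell: str, T: int, rng: np.random.Generator, seed: int
) -> SequenceModelConfig:
    return SequenceModelConfig(
        f=64,
        hidden=int(rng.choice(HIDDEN_CHOICES)),
        layers=int(rng.choice(LAYER_CHOICES)),
        cell=cell,
        dropout=float(rng.choice(DROPOUT_CHOICES)),
        learning_rate=float(rng.choice(LR_CHOICES)),
        batch_size=int(rng.choice(BATCH_CHOICES)),
        T=T,
        seed=seed % (2**31 - 1),
    )


def _eval_candidate(
    candidate,
    family: str,
    task: str,
    X: np.ndarray,
    target,
    inner_pairs,
    grid,
    epochs_inner: int,
    seed: int,
):
    """Mean inner-validation score of one candidate (higher is better)."""
    from .tabular import fit_predict_classification, fit_predict_regression

    scores = []
    for tr, va in inner_pairs:
        fm_tr = FeatureMatrix(ids=[str(i) for i in tr], X=X[tr], columns=["x"] * X.shape[1])
        fm_va = FeatureMatrix(ids=[str(i) for i in va], X=X[va], columns=["x"] * X.shape[1])
        if task == "regression":
            pred = fit_predict_regression(fm_tr, target[tr], fm_va, candidate, seed)
            scores.append(-rmse(target[va], pred))
        elif task == "classification":
            pred, s = fit_predict_classification(fm_tr, target[tr], fm_va, candidate, seed)
            scores.append(f1_score(target[va], pred, zero_division=0))
        elif family in ("gbdt_time", "gbdt_no_time"):
            P = fit_predict_profile_with_time(
                fm_tr,
                target[tr],
                fm_va,
                grid,
                candidate,
                include_time=(family == "gbdt_time"),
                seed=seed,
            )
            scores.append(-rmse(target[va], P))
        else:  # sequence model
            model = train_sequence_model(
                X[tr], target[tr], candidate, epochs=epochs_inner
            )
            scores.append(-rmse(target[va], model.predict(X[va])))
    return float(np.mean(scores))


def tune_hyperparameters(
    X: np.ndarray,
    target,
    family: str,
    task: str,
    inner_pairs,
    trials: int = DEFAULT_TRIALS,
    rng: np.random.Generator | None = None,
    candidates=None,
    grid=None,
    epochs_inner: int = EPOCHS_INNER,
    seed: int = 42,
):
    """Seeded random search over the family's space; returns (best, score).

    ``candidates`` overrides sampling with an explicit list.  The score is
    the mean across the inner validation folds: negated RMSE for
    regression/profile tasks, F1 for classification.
    """
    if trials < 1 and candidates is None:
        raise ConfigError("need trials >= 1")
    rng = rng or np.random.default_rng(seed)
    if candidates is None:
        if family in ("sequence_lstm", "sequence_gru"):
            cell = "lstm" if family == "sequence_lstm" else "gru"
            candidates = [
                _sample_sequence_config(cell, len(grid), rng, seed)
                for _ in range(trials)
            ]
        elif family in ("gbdt_time", "gbdt_no_time"):
            candidates = [sample_spec("gbdt", "regression", rng) for _ in range(trials)]
        else:
            candidates = [sample_spec(family, task, rng) for _ in range(trials)]
    if not candidates:
        raise ConfigError("empty candidate list")
    best, best_score = None, -np.inf
    for cand in candidates:
        score = _eval_candidate(
            cand, family, task, X, target, inner_pairs, grid, epochs_inner, seed
        )
        if score > best_score:
            best, best_score = cand, score
    return best, best_score


# ------------------------------------------------------------------- reports
@dataclass
class CVReport:
    """Per-fold and aggregated nested-CV results for one model family."""

    task: str
    family: str
    fold_metrics: pd.DataFrame
    aggregate: pd.DataFrame
    chosen: list
    pooled: pd.DataFrame | None = None
    pooled_profiles: tuple | None = None  # (ids, R_true, R_pred)
    models: list = field(default_factory=list)

    def metric_mean(self, name: str) -> float:
        row = self.aggregate[self.aggregate["metric"] == name]
        return float(row["mean"].iloc[0])


def _aggregate(fold_metrics: pd.DataFrame) -> pd.DataFrame:
    rows = [
        {
            "metric": c,
            "mean": float(fold_metrics[c].mean()),
            "sd": float(fold_metrics[c].std(ddof=0)),
        }
        for c in fold_metrics.columns
        if c != "fold"
    ]
    return pd.DataFrame(rows)


def _positions(train_idx: np.ndarray, abs_idx: np.ndarray) -> np.ndarray:
    lookup = {v: i for i, v in enumerate(train_idx)}
    return np.array([lookup[v] for v in abs_idx], dtype=int)


def run_nested_cv(
    feature_frame: pd.DataFrame,
    target,
    task: str,
    families,
    trials: int = DEFAULT_TRIALS,
    seed: int = 42,
    grid=None,
    stratify_labels=None,
    n_outer: int = N_OUTER,
    n_inner: int = N_INNER,
    epochs_inner: int = EPOCHS_INNER,
    epochs_outer: int = EPOCHS_OUTER,
    store_models: bool = False,
) -> dict[str, CVReport]:
    """Run the full nested-CV protocol for each requested model family.

    ``task`` is "regression" (target: 1-d array), "classification"
    (target: binary labels) or "profile" (target: (N, T) matrix with
    ``grid`` giving the normalized time grid).  Classification and
    profile folds are stratified — by label and by AUC class of the true
    profile respectively — to keep the imbalanced classes represented in
    every fold.
    """
    target = np.asarray(target)
    n = len(feature_frame)
    if task == "classification":
        strat = target
    elif task == "profile":
        if grid is None:
            raise ConfigError("profile task requires the normalized time grid")
        strat = np.array(
            [
                assign_profile_type(
                    compute_auc(NormalizedProfile("s", np.asarray(grid), row))
                ).release_type
                for row in target
            ]
        )
    else:
        strat = stratify_labels
    plan = make_nested_folds(n, task, seed, labels=strat, n_outer=n_outer, n_inner=n_inner)

    reports = {}
    for family in families:
        fold_rows, chosen, models = [], [], []
        pooled_parts = []
        pooled_prof_ids, pooled_R, pooled_P = [], [], []
        for k in range(n_outer):
            te, tr = plan.outer_test[k], plan.outer_train[k]
            fm_train, stats = encode_and_standardize(feature_frame.iloc[tr])
            fm_test, _ = encode_and_standardize(feature_frame.iloc[te], stats)
            X_tr = fm_train.X
            inner_pairs = [
                (_positions(tr, a), _positions(tr, b)) for a, b in plan.inner[k]
            ]
            rng = _family_stream(seed, k, family)
            best, _ = tune_hyperparameters(
                X_tr,
                target[tr],
                family,
                task,
                inner_pairs,
                trials=trials,
                rng=rng,
                grid=grid,
                epochs_inner=epochs_inner,
                seed=seed,
            )
            row = {"fold": k}
            if task == "regression":
                model = make_model(best, seed)
                model.fit(X_tr, target[tr].astype(float))
                pred = np.asarray(model.predict(fm_test.X), dtype=float)
                row["rmse"] = rmse(target[te], pred)
                pooled_parts.append(
                    pd.DataFrame(
                        {"formulation_id": fm_test.ids, "y_true": target[te], "y_pred": pred}
                    )
                )
                chosen.append(best.hyperparameters)
            elif task == "classification":
                model = make_model(best, seed)
                model.fit(X_tr, target[tr].astype(int))
                scores = model.predict_proba(fm_test.X)[:, 1]
                pred = (scores > 0.5).astype(int)
                row.update(classification_metrics(target[te], pred, scores))
                pooled_parts.append(
                    pd.DataFrame(
                        {
                            "formulation_id": fm_test.ids,
                            "y_true": target[te],
                            "y_pred": pred,
                            "score": scores,
                        }
                    )
                )
                chosen.append(best.hyperparameters)
            else:  # profile
                if family in ("gbdt_time", "gbdt_no_time"):
                    include_time = family == "gbdt_time"
                    P = fit_predict_profile_with_time(
                        fm_train,
                        target[tr],
                        fm_test,
                        grid,
                        best,
                        include_time=include_time,
                        seed=seed,
                    )
                    model = best
                    chosen.append(best.hyperparameters)
                else:
                    cfg = replace(best, epochs=epochs_outer)
                    model = train_sequence_model(
                        X_tr, target[tr].astype(float), cfg, epochs=epochs_outer
                    )
                    P = predict_release_profile(model, fm_test).R_hat
                    chosen.append(
                        {
                            key: getattr(best, key)
                            for key in (
                                "hidden",
                                "layers",
                                "cell",
                                "dropout",
                                "learning_rate",
                                "batch_size",
                            )
                        }
                    )
                row["rmse"] = rmse(target[te], P)
                pooled_prof_ids.extend(fm_test.ids)
                pooled_R.append(target[te])
                pooled_P.append(P)
            fold_rows.append(row)
            if store_models:
                models.append({"fold": k, "model": model, "stats": stats, "test_idx": te})

        fold_metrics = pd.DataFrame(fold_rows)
        report = CVReport(
            task=task,
            family=family,
            fold_metrics=fold_metrics,
            aggregate=_aggregate(fold_metrics),
            chosen=chosen,
            models=models,
        )
        if pooled_parts:
            report.pooled = pd.concat(pooled_parts, ignore_index=True)
        if pooled_R:
            report.pooled_profiles = (
                pooled_prof_ids,
                np.vstack(pooled_R),
                np.vstack(pooled_P),
            )
        reports[family] = report
    return reports


def pooled_pearson(report: CVReport) -> float:
    """Pearson correlation over the pooled out-of-fold predictions."""
    if report.pooled is None:
        raise LaiReleaseError("report holds no pooled scalar predictions")
    return pearson_correlation(report.pooled["y_true"], report.pooled["y_pred"])
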
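"""End-to-end pipeline: preprocess -> early / classify / profile -> explain.

Each stage reads the canonical files, runs the corresponding analysis and
writes delimited-text tables under the output directory, together with a
reproducibility manifest (config hash, seeds, package versions, stage
timings).  Stages log their progress and any stage error aborts the run
with the failing stage named.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import LaiReleaseError
from .evaluation import (
    pooled_pearson,
    rmse_by_auc_group,
    run_nested_cv,
)
from .explain import (
    attributions_over_folds,
    directional_effect_summary,
    rank_features,
)
from .io import (
    RunConfig,
    check_cross_reference,
    read_formulations,
    read_profiles,
    write_formulations,
    write_normalized_matrix,
    write_profiles,
)
from .profiles import (
    assign_profile_type,
    compute_auc,
    early_release_targets,
    resample_profile,
    uniform_grid,
)
from .records import records_to_frame
from .synthetic import SyntheticConfig, generate_dataset

log = logging.getLogger("lairelease")

#: Config family token -> tabular family per task.
_REG_FAMILY = {"linear": "linear_regression", "random_forest": "random_forest", "gbdt": "gbdt"}
_CLF_FAMILY = {"linear": "logistic_linear", "random_forest": "random_forest", "gbdt": "gbdt"}


def simulate(config: RunConfig, outdir: Path) -> None:
    """Generate a synthetic study and write its canonical files + truth."""
    syn = config.synthetic
    scfg = SyntheticConfig(
        mixture=tuple(syn.get("mixture", (0.26, 0.74))),
        noise_sd=float(syn.get("noise_sd", 0.02)),
    )
    ds = generate_dataset(int(syn.get("n", 321)), config.seed, scfg)
    write_formulations(ds.records, outdir / "features.csv")
    write_profiles(ds.profiles, outdir / "profiles.csv")
    ds.truth.to_csv(outdir / "truth.csv", index=False)
    log.info("simulated %d formulations -> %s", len(ds.records), outdir)


def _load_inputs(config: RunConfig, outdir: Path):
    features = config.features or str(outdir / "features.csv")
    profiles_path = config.profiles or str(outdir / "profiles.csv")
    records, frame = read_formulations(features, config.column_map)
    profiles = read_profiles(profiles_path, config.times_in_days)
    check_cross_reference(records, profiles)
    order = {fid: i for i, fid in enumerate(frame["formulation_id"])}
    profiles = sorted(profiles, key=lambda p: order[p.formulation_id])
    return records, frame, profiles


def preprocess(config: RunConfig, outdir: Path):
    """Resample profiles, compute AUC labels and early-release targets."""
    records, frame, profiles = _load_inputs(config, outdir)
    normalized = [
        resample_profile(p, config.T, config.magnitude_mode) for p in profiles
    ]
    R = np.vstack([p.values for p in normalized])
    grid = uniform_grid(config.T)
    labels = np.array(
        [assign_profile_type(compute_auc(p)).release_type for p in normalized]
    )
    early = pd.DataFrame([early_release_targets(p).as_dict() for p in profiles])
    write_normalized_matrix(normalized, outdir / "normalized_profiles.csv")
    early.to_csv(outdir / "early_targets.csv", index=False)
    pd.DataFrame(
        {
            "formulation_id": [p.formulation_id for p in normalized],
            "auc": [compute_auc(p) for p in normalized],
            "release_type": labels,
        }
    ).to_csv(outdir / "release_types.csv", index=False)
    log.info(
        "preprocess: %d profiles on T=%d grid, class split %d:%d",
        len(profiles),
        config.T,
        int((labels == 0).sum()),
        int((labels == 1).sum()),
    )
    return frame, R, grid, labels, early


def _cv_kwargs(config: RunConfig) -> dict:
    return dict(
        trials=config.trials,
        seed=config.seed,
        n_outer=config.n_outer,
        n_inner=config.n_inner,
        epochs_inner=config.epochs_inner,
        epochs_outer=config.epochs_outer,
    )


def run_early(config, outdir, frame, early: pd.DataFrame) -> None:
    """Early fractional-release regression at each configured hour."""
    rows = []
    for hour in config.early_hours:
        col = f"frac_{int(hour)}h"
        families = [_REG_FAMILY[f] for f in config.families if f in _REG_FAMILY]
        reports = run_nested_cv(
            frame, early[col].to_numpy(), "regression", families, **_cv_kwargs(config)
        )
        for family, rep in reports.items():
            rows.append(
                {
                    "hour": int(hour),
                    "model": family,
                    "rmse_mean": rep.metric_mean("rmse"),
                    "rmse_sd": float(rep.aggregate.loc[rep.aggregate["metric"] == "rmse", "sd"].iloc[0]),
                    "pearson_pooled": pooled_pearson(rep),
                }
            )
            rep.fold_metrics.to_csv(
                outdir / f"early_{int(hour)}h_{family}_folds.csv", index=False
            )
    pd.DataFrame(rows).to_csv(outdir / "early_metrics.csv", index=False)


def run_classify(config, outdir, frame, labels) -> dict:
    """Release-type classification; returns reports for the explain stage."""
    families = [_CLF_FAMILY[f] for f in config.families if f in _CLF_FAMILY]
    reports = run_nested_cv(
        frame, labels, "classification", families, store_models=True, **_cv_kwargs(config)
    )
    rows = []
    for family, rep in reports.items():
        entry = {"model": family}
        for metric in ("accuracy", "auroc", "precision", "recall", "f1"):
            entry[f"{metric}_mean"] = rep.metric_mean(metric)
        rows.append(entry)
        rep.fold_metrics.to_csv(outdir / f"classify_{family}_folds.csv", index=False)
    pd.DataFrame(rows).to_csv(outdir / "classify_metrics.csv", index=False)
    return reports


def run_profile(config, outdir, frame, R, grid) -> None:
    """Complete-profile prediction with the configured profile families."""
    reports = run_nested_cv(
        frame, R, "profile", config.profile_families, grid=grid, **_cv_kwargs(config)
    )
    rows = []
    for family, rep in reports.items():
        rows.append(
            {
                "model": family,
                "rmse_mean": rep.metric_mean("rmse"),
                "rmse_sd": float(rep.aggregate.loc[rep.aggregate["metric"] == "rmse", "sd"].iloc[0]),
            }
        )
        ids, R_true, R_pred = rep.pooled_profiles
        groups = rmse_by_auc_group(R_true, R_pred, grid)
        groups.insert(0, "model", family)
        groups.to_csv(outdir / f"profile_{family}_auc_groups.csv", index=False)
    pd.DataFrame(rows).to_csv(outdir / "profile_metrics.csv", index=False)


def run_explain(config, outdir, frame, early, labels) -> None:
    """SHAP rankings and directions for the GBDT 24 h regressor and classifier."""
    kw = _cv_kwargs(config)
    reg_reports = run_nested_cv(
        frame, early["frac_24h"].to_numpy(), "regression", ["gbdt"],
        store_models=True, **kw
    )
    clf_reports = run_nested_cv(
        frame, labels, "classification", ["gbdt"], store_models=True, **kw
    )
    for tag, rep in (("early24h_gbdt", reg_reports["gbdt"]), ("classify_gbdt", clf_reports["gbdt"])):
        att = attributions_over_folds(rep, frame)
        ranked = rank_features(att)
        directions = directional_effect_summary(att)
        table = ranked.merge(directions, on="feature")
        table.to_csv(outdir / f"explain_{tag}.csv", index=False)


def run_pipeline(config: RunConfig, do_simulate: bool = False) -> Path:
    """Execute the configured stages in order and write a manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    timings, stage = {}, "setup"
    try:
        if do_simulate or (config.features is None and not (outdir / "features.csv").exists()):
            stage = "simulate"
            t0 = time.perf_counter()
            simulate(config, outdir)
            timings[stage] = time.perf_counter() - t0
        stage = "preprocess"
        t0 = time.perf_counter()
        frame, R, grid, labels, early = preprocess(config, outdir)
        timings[stage] = time.perf_counter() - t0
        if "early" in config.tasks:
            stage = "early"
            t0 = time.perf_counter()
            run_early(config, outdir, frame, early)
            timings[stage] = time.perf_counter() - t0
        if "classify" in config.tasks:
            stage = "classify"
            t0 = time.perf_counter()
            run_classify(config, outdir, frame, labels)
            timings[stage] = time.perf_counter() - t0
        if "profile" in config.tasks:
            stage = "profile"
            t0 = time.perf_counter()
            run_profile(config, outdir, frame, R, grid)
            timings[stage] = time.perf_counter() - t0
        if "explain" in config.tasks:
            stage = "explain"
            t0 = time.perf_counter()
            run_explain(config, outdir, frame, early, labels)
            timings[stage] = time.perf_counter() - t0
    except LaiReleaseError as err:
        raise LaiReleaseError(f"stage {stage!r} failed: {err}") from err
    stage = "manifest"
    cfg = asdict(config)
    manifest = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": config.seed,
        "versions": {
            "lairelease": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("pipeline complete -> %s", outdir)
    return outdir
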
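"""Readers and writers for feature tables, release profiles and run configs.

Canonical formats are comma-delimited text with a required header:

* feature table — one row per formulation; ``formulation_id`` plus the 11
  descriptor columns (display names like "Encapsulation Efficiency" or
  their snake_case equivalents; a column-mapping block adapts external
  headers).
* profile file — long format with columns ``formulation_id``, ``time_h``,
  ``cumulative_release_pct``; rows may be unsorted, duplicate times are
  collapsed by their mean, day-denominated times are converted with a
  config flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigError,
    CrossReferenceError,
    DegenerateProfileError,
    SchemaError,
)
from .profiles import NormalizedProfile, RawReleaseProfile
from .records import (
    DISPLAY_NAMES,
    FEATURE_COLUMNS,
    FormulationRecord,
    frame_to_records,
    records_to_frame,
)

_DISPLAY_TO_INTERNAL = {v: k for k, v in DISPLAY_NAMES.items()}

PROFILE_COLUMNS = ["formulation_id", "time_h", "cumulative_release_pct"]

_PCT_COLUMNS = ("encapsulation_efficiency", "loading_capacity")


def read_formulations(path, column_map: dict | None = None):
    """Read a feature table; returns (records, canonical DataFrame).

    Headers may use the documented display names or internal snake_case
    names; ``column_map`` maps external header -> canonical name first.
    Percent columns are validated to lie in [0, 110].
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    df = df.rename(columns=_DISPLAY_TO_INTERNAL)
    for col in ["formulation_id"] + FEATURE_COLUMNS:
        if col not in df.columns:
            display = DISPLAY_NAMES.get(col, col)
            raise SchemaError(f"feature table missing required column {display!r}")
    numeric = [c for c in FEATURE_COLUMNS if c != "formulation_method"]
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            line = int(bad[0]) + 2  # header is line 1
            raise SchemaError(
                f"unparseable numeric in column {col!r} at line {line}: "
                f"{df.loc[bad[0], col]!r}"
            )
        df[col] = parsed
    for col in _PCT_COLUMNS:
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 110)).any():
            raise SchemaError(f"column {col!r} must lie in [0, 110] percent")
    df["formulation_id"] = df["formulation_id"].astype(str)
    canonical = df[["formulation_id"] + FEATURE_COLUMNS].copy()
    return frame_to_records(canonical), canonical


def write_formulations(records, path) -> None:
    """Write records as a canonical comma-delimited feature table."""
    frame = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    # %.17g keeps the text round-trip exact at double precision
    frame.to_csv(path, index=False, float_format="%.17g")


def read_profiles(path, times_in_days: bool = False) -> list[RawReleaseProfile]:
    """Read a long-format profile file into per-formulation profiles.

    Rows are grouped by id and sorted by time; duplicate (id, time) rows
    collapse to their mean with a warning; a profile with fewer than two
    distinct times raises a degenerate-profile error naming the id.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    for col in PROFILE_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"profile file missing required column {col!r}")
    df["formulation_id"] = df["formulation_id"].astype(str)
    for col in PROFILE_COLUMNS[1:]:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"unparseable numeric in column {col!r} at line {int(bad[0]) + 2}"
            )
        df[col] = parsed
    if times_in_days:
        df["time_h"] = df["time_h"] * 24.0
    profiles = []
    for fid, group in df.groupby("formulation_id", sort=True):
        if group.duplicated("time_h").any():
            warnings.warn(
                f"profile {fid!r}: duplicate time points collapsed by mean",
                stacklevel=2,
            )
            group = (
                group.groupby("time_h", as_index=False)["cumulative_release_pct"]
                .mean()
                .assign(formulation_id=fid)
            )
        group = group.sort_values("time_h")
        if len(group) < 2:
            raise DegenerateProfileError(
                f"profile {fid!r} has fewer than 2 distinct time points"
            )
        profiles.append(
            RawReleaseProfile(
                fid,
                group["time_h"].to_numpy(dtype=float),
                group["cumulative_release_pct"].to_numpy(dtype=float),
            )
        )
    return profiles


def write_profiles(profiles, path) -> None:
    """Write profiles in the canonical long format."""
    rows = [
        {
            "formulation_id": p.formulation_id,
            "time_h": t,
            "cumulative_release_pct": r,
        }
        for p in profiles
        for t, r in zip(p.times, p.releases)
    ]
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_normalized_matrix(profiles: list[NormalizedProfile], path) -> None:
    """Write resampled profiles as a matrix, header row = grid values."""
    grid = profiles[0].grid
    df = pd.DataFrame(
        np.vstack([p.values for p in profiles]),
        columns=[f"{g:.6g}" for g in grid],
    )
    df.insert(0, "formulation_id", [p.formulation_id for p in profiles])
    df.to_csv(path, index=False)


def check_cross_reference(records, profiles) -> None:
    """Every profile id must have a formulation record and vice versa."""
    rec_ids = {r.formulation_id for r in records}
    prof_ids = {p.formulation_id for p in profiles}
    orphans = sorted(prof_ids - rec_ids)
    if orphans:
        raise CrossReferenceError(
            f"profiles without formulation records: {orphans[:5]}"
        )
    missing = sorted(rec_ids - prof_ids)
    if missing:
        raise CrossReferenceError(
            f"formulation records without profiles: {missing[:5]}"
        )


# ----------------------------------------------------------------- run config
_KNOWN_KEYS = {
    "features",
    "profiles",
    "outdir",
    "T",
    "magnitude_mode",
    "tasks",
    "families",
    "profile_families",
    "trials",
    "seed",
    "epochs_inner",
    "epochs_outer",
    "n_outer",
    "n_inner",
    "early_hours",
    "times_in_days",
    "column_map",
    "synthetic",
    "log_level",
}
_KNOWN_SYNTHETIC_KEYS = {"n", "mixture", "noise_sd"}


@dataclass
class RunConfig:
    """Validated run configuration with the protocol constants as defaults."""

    features: str | None = None
    profiles: str | None = None
    outdir: str = "out"
    T: int = 101
    magnitude_mode: str = "max"
    tasks: list = field(default_factory=lambda: ["early", "classify", "profile", "explain"])
    families: list = field(default_factory=lambda: ["linear", "random_forest", "gbdt"])
    profile_families: list = field(
        default_factory=lambda: ["gbdt_time", "gbdt_no_time", "sequence_lstm", "sequence_gru"]
    )
    trials: int = 50
    seed: int = 42
    epochs_inner: int = 250
    epochs_outer: int = 500
    n_outer: int = 10
    n_inner: int = 2
    early_hours: tuple = (24.0, 48.0, 72.0)
    times_in_days: bool = False
    column_map: dict | None = None
    synthetic: dict = field(default_factory=lambda: {"n": 321, "mixture": [0.26, 0.74], "noise_sd": 0.02})
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.T < 2:
            raise ConfigError("T must be >= 2")
        if self.magnitude_mode not in ("max", "percent"):
            raise ConfigError(f"unknown magnitude_mode {self.magnitude_mode!r}")
        if self.trials < 1 or self.n_outer < 2 or self.n_inner < 2:
            raise ConfigError("trials >= 1, n_outer >= 2 and n_inner >= 2 required")
        unknown = set(self.synthetic) - _KNOWN_SYNTHETIC_KEYS
        if unknown:
            raise SchemaError(f"unknown synthetic config keys: {sorted(unknown)}")


def load_run_config(path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys up front."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError("run config must be a mapping")
    unknown = set(data) - _KNOWN_KEYS
    if unknown:
        raise SchemaError(f"unknown config keys: {sorted(unknown)}")
    config = RunConfig(**data)
    config.validate()
    return config
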
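"""Time-independent representation of cumulative drug release profiles.

In-vitro release profiles of long-acting injectables are measured at
irregular times and over wildly different durations (days to months).  To
make them comparable, each profile's time axis is min-max normalized to
[0, 1] and its release values are linearly interpolated onto a fixed
uniform grid.  The area under the resulting unit-square curve (AUC) is a
pure shape descriptor: 0.5 is a perfectly linear (monophasic) release,
values above 0.5 are front-loaded (burst-like) and values at or below 0.5
are delayed.  Profiles are labelled with a binary release type on that
basis (class 0: AUC <= 0.5, class 1: AUC > 0.5).

The module also interpolates fractional release at the early 24/48/72 h
time points used to study burst behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateProfileError,
    InsufficientDurationError,
    InvalidDescriptorError,
    OutOfBracketError,
)

#: Default number of uniform grid points (step 0.01 on [0, 1]).
DEFAULT_GRID_SIZE = 101

#: Early release time points, hours.
EARLY_HOURS = (24.0, 48.0, 72.0)


@dataclass(frozen=True)
class RawReleaseProfile:
    """Irregularly sampled cumulative release measurements for one formulation.

    Parameters
    ----------
    formulation_id
        Opaque identifier linking the profile to its formulation record.
    times
        Sampling times in hours, strictly increasing, first time >= 0.
    releases
        Cumulative drug released at each time.  Values are percent of
        loaded drug for raw input (``[0, 110]``, tolerating small
        over-100 assay noise) or fractions after magnitude normalization.
    """

    formulation_id: str
    times: np.ndarray
    releases: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.releases, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "releases", r)
        if t.ndim != 1 or r.ndim != 1 or len(t) != len(r):
            raise DegenerateProfileError(
                f"profile {self.formulation_id!r}: times and releases must be "
                f"1-d and equally long (got {t.shape} vs {r.shape})"
            )
        if len(t) < 2:
            raise DegenerateProfileError(
                f"profile {self.formulation_id!r}: needs >= 2 points, got {len(t)}"
            )
        if not np.all(np.diff(t) > 0):
            raise DegenerateProfileError(
                f"profile {self.formulation_id!r}: times must be strictly increasing"
            )
        if t[0] < 0:
            raise DegenerateProfileError(
                f"profile {self.formulation_id!r}: first time must be >= 0"
            )

    @property
    def duration_h(self) -> float:
        return float(self.times[-1])


@dataclass(frozen=True)
class NormalizedProfile:
    """Release fractions on a uniform normalized-time grid in [0, 1]."""

    formulation_id: str
    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "values", v)
        if len(g) != len(v):
            raise DegenerateProfileError("grid and values must be equally long")
        if len(g) < 2 or g[0] != 0.0 or g[-1] != 1.0:
            raise DegenerateProfileError("grid must run from 0 to 1 inclusive")


@dataclass(frozen=True)
class ProfileTypeLabel:
    """AUC shape descriptor and its binary release-type class.

    ``release_type`` is 0 iff ``auc <= 0.5`` (monophasic / delayed biphasic /
    triphasic) and 1 otherwise (burst biphasic).
    """

    auc: float
    release_type: int


@dataclass(frozen=True)
class EarlyReleaseTargets:
    """Fractional release at the early 24/48/72 h time points."""

    formulation_id: str
    frac_24h: float
    frac_48h: float
    frac_72h: float

    def as_dict(self) -> dict:
        return {
            "formulation_id": self.formulation_id,
            "frac_24h": self.frac_24h,
            "frac_48h": self.frac_48h,
            "frac_72h": self.frac_72h,
        }


def uniform_grid(T: int = DEFAULT_GRID_SIZE) -> np.ndarray:
    """Uniform normalized-time grid of ``T`` points including both endpoints."""
    if T < 2:
        raise DegenerateProfileError(f"grid size must be >= 2, got {T}")
    return np.linspace(0.0, 1.0, T)


def normalize_time(times) -> np.ndarray:
    """Min-max normalize a strictly increasing time axis onto [0, 1].

    ``t_norm = (t - t_min) / (t_max - t_min)``.  The output is invariant
    to any affine rescaling of the input axis (unit changes, shifted
    starting point).
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise DegenerateProfileError("need at least 2 time points")
    if not np.all(np.diff(t) > 0):
        if t.max() == t.min():
            raise DegenerateProfileError("zero time range (t_max == t_min)")
        raise DegenerateProfileError("times must be strictly increasing")
    return (t - t[0]) / (t[-1] - t[0])


def interp_point(t0: float, y0: float, t1: float, y1: float, t_int: float) -> float:
    """Linearly interpolate a release value between two bracketing knots.

    ``y_int = y0 + (t_int - t0) / (t1 - t0) * (y1 - y0)``; exact at the
    knots.  Extrapolation is refused: ``t_int`` must lie in ``[t0, t1]``.
    """
    if not t0 < t1:
        raise OutOfBracketError(f"need t0 < t1, got [{t0}, {t1}]")
    if not (t0 <= t_int <= t1):
        raise OutOfBracketError(f"t_int={t_int} outside bracket [{t0}, {t1}]")
    return y0 + (t_int - t0) / (t1 - t0) * (y1 - y0)


def normalize_magnitude(
    profile: RawReleaseProfile, mode: str = "max"
) -> RawReleaseProfile:
    """Convert release magnitudes to fractions.

    mode ``"percent"`` divides by 100 (values stay in [0, 1.1] for inputs
    tolerating slight over-100 assay noise); mode ``"max"`` divides by the
    profile's own maximum so every profile ends exactly at 1 and the AUC
    becomes a pure shape descriptor comparable across plateaus.
    """
    r = profile.releases
    if np.any(r < 0):
        raise DegenerateProfileError(
            f"profile {profile.formulation_id!r}: negative release values"
        )
    if mode == "percent":
        scaled = r / 100.0
    elif mode == "max":
        m = r.max()
        if m == 0:
            raise DegenerateProfileError(
                f"profile {profile.formulation_id!r}: all-zero release under max mode"
            )
        scaled = r / m
    else:
        raise DegenerateProfileError(f"unknown magnitude mode {mode!r}")
    return RawReleaseProfile(profile.formulation_id, profile.times, scaled)


def _with_origin_anchor(profile: RawReleaseProfile) -> RawReleaseProfile:
    """Prepend a (t=0, release=0) point when the first sample is late.

    Cumulative release is physically zero at injection, so a profile whose
    first measurement falls after t=0 is anchored at the origin before
    interpolation.
    """
    if profile.times[0] > 0:
        return RawReleaseProfile(
            profile.formulation_id,
            np.concatenate([[0.0], profile.times]),
            np.concatenate([[0.0], profile.releases]),
        )
    return profile


def resample_profile(
    profile: RawReleaseProfile,
    T: int = DEFAULT_GRID_SIZE,
    magnitude_mode: str = "max",
    prepend_origin: bool = True,
    enforce_monotone: bool = False,
) -> NormalizedProfile:
    """Resample a raw profile onto a fixed uniform normalized-time grid.

    Steps: optionally anchor at the origin, normalize magnitude, min-max
    normalize time, then linearly interpolate onto ``T`` uniform grid
    points including both endpoints.  Grid points coinciding with knots
    reproduce the knot values exactly, and monotone inputs stay monotone.

    ``enforce_monotone`` additionally clips values to a running maximum;
    off by default since small assay-noise dips are real data features.
    """
    frac = normalize_magnitude(profile, magnitude_mode)
    if prepend_origin:
        frac = _with_origin_anchor(frac)
    t_norm = normalize_time(frac.times)
    grid = uniform_grid(T)
    values = np.interp(grid, t_norm, frac.releases)
    if enforce_monotone:
        values = np.maximum.accumulate(values)
    return NormalizedProfile(profile.formulation_id, grid, values)


def compute_auc(profile: NormalizedProfile) -> float:
    """Trapezoidal area under a normalized profile on [0, 1].

    0.5 for a perfectly linear release; 1.0 for instantaneous release.
    """
    return float(np.trapezoid(profile.values, profile.grid))


def assign_profile_type(auc: float) -> ProfileTypeLabel:
    """Binary release-type label from the AUC shape descriptor.

    Class 0 for AUC <= 0.5 (boundary inclusive), class 1 otherwise.
    """
    if not np.isfinite(auc) or auc < 0:
        raise InvalidDescriptorError(f"AUC must be finite and >= 0, got {auc}")
    return ProfileTypeLabel(auc=float(auc), release_type=0 if auc <= 0.5 else 1)


def fractional_release_at(
    profile: RawReleaseProfile,
    hour: float,
    magnitude_mode: str = "percent",
    prepend_origin: bool = True,
) -> float:
    """Interpolate the release fraction at an early time point (hours).

    Works on the raw hour axis after magnitude normalization.  If the
    requested hour precedes the first sample, interpolation runs from an
    assumed (0 h, 0) anchor.  A profile that ends before ``hour`` raises
    :class:`InsufficientDurationError`.
    """
    if profile.duration_h < hour:
        raise InsufficientDurationError(
            f"profile {profile.formulation_id!r} ends at {profile.duration_h} h, "
            f"before requested {hour} h"
        )
    frac = normalize_magnitude(profile, magnitude_mode)
    if prepend_origin:
        frac = _with_origin_anchor(frac)
    if hour < frac.times[0]:
        # first sample still after the requested hour and anchoring disabled
        return float(
            interp_point(0.0, 0.0, frac.times[0], frac.releases[0], hour)
        )
    idx = int(np.searchsorted(frac.times, hour, side="right") - 1)
    if frac.times[idx] == hour:
        return float(frac.releases[idx])
    return float(
        interp_point(
            frac.times[idx],
            frac.releases[idx],
            frac.times[idx + 1],
            frac.releases[idx + 1],
            hour,
        )
    )


def early_release_targets(
    profile: RawReleaseProfile, magnitude_mode: str = "percent"
) -> EarlyReleaseTargets:
    """Fractional release at 24, 48 and 72 hours for one profile."""
    f24, f48, f72 = (
        fractional_release_at(profile, h, magnitude_mode) for h in EARLY_HOURS
    )
    return EarlyReleaseTargets(profile.formulation_id, f24, f48, f72)
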
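"""Per-participant perceptual maps and the group-level inferential statistics.

The analysis chain per participant (and posture condition) is:

1. exclude trials whose click fell outside the board square;
2. average judged positions per stimulus location -> the perceptual map;
3. Procrustes distance of the map to the actual grid, with an empirical
   p-value against the Monte-Carlo null;
4. per-axis OLS of judged on actual coordinate -> localization slopes
   (0 = no positional information, 1 = veridical);
5. per-location, per-axis standard deviations of judgments -> variable error.

At the group level, slopes are tested against 0 per axis (one-sample t, with
Cohen's d), the two axes are compared (paired t with dz, Pearson r across
participants), variable errors are compared between axes (paired t), and the
grand-mean Procrustes distance is tested against the resampled group null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .errors import (
    DegenerateDataError,
    InsufficientRepetitionsError,
    MissingLocationError,
)
from .geometry import PointSet2D, StimulusGrid, procrustes_align
from .nulls import NullDistribution, empirical_p

__all__ = [
    "PerceptualMap",
    "AxisRegression",
    "VariableError",
    "GroupTest",
    "ParticipantStats",
    "exclude_outside",
    "build_map",
    "axis_slopes",
    "variable_error",
    "one_sample_t",
    "one_sample_t_from_summary",
    "paired_t",
    "pearson_r",
    "analyze_participant",
    "analyze_cohort",
    "analyze_group",
]

Axis = Literal["mediolateral", "proximodistal"]
_AXIS_COLUMN = {"mediolateral": "x", "proximodistal": "y"}


@dataclass(frozen=True)
class PerceptualMap:
    """Per-location mean judged positions for one participant/condition."""

    participant: str
    condition: str
    means: PointSet2D
    n_valid: np.ndarray

    def __post_init__(self) -> None:
        n_valid = np.asarray(self.n_valid, dtype=int)
        if n_valid.shape != (len(self.means),):
            raise ValueError("n_valid must hold one count per location")
        if np.any(n_valid < 1):
            raise ValueError("every location needs at least one valid trial")
        object.__setattr__(self, "n_valid", n_valid)


@dataclass(frozen=True)
class AxisRegression:
    """OLS fit of judged on actual coordinate along one board axis."""

    axis: Axis
    slope: float
    intercept: float
    n_trials: int


@dataclass(frozen=True)
class VariableError:
    """Per-location SDs of judgments along one axis, and their mean."""

    axis: Axis
    per_location_sd: np.ndarray
    mean_sd: float


@dataclass(frozen=True)
class GroupTest:
    """A group-level test statistic with df, two-tailed p and effect size."""

    statistic: float
    df: int
    p: float
    effect: float | None
    effect_kind: Literal["d", "dz", None]
    n: int

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "df": self.df,
            "p": self.p,
            "effect": self.effect,
            "effect_kind": self.effect_kind,
            "n": self.n,
        }


@dataclass(frozen=True)
class ParticipantStats:
    """Bundled per-participant results for one condition."""

    participant: str
    condition: str
    n_trials: int
    n_excluded: int
    exclusion_rate: float
    procrustes_distance: float
    procrustes_p: float
    slope_x: AxisRegression
    slope_y: AxisRegression
    ve_x: VariableError
    ve_y: VariableError

    def to_row(self) -> dict:
        return {
            "participant": self.participant,
            "condition": self.condition,
            "n_trials": self.n_trials,
            "n_excluded": self.n_excluded,
            "exclusion_rate": self.exclusion_rate,
            "procrustes_distance": self.procrustes_distance,
            "procrustes_p": self.procrustes_p,
            "slope_mediolateral": self.slope_x.slope,
            "intercept_mediolateral": self.slope_x.intercept,
            "slope_proximodistal": self.slope_y.slope,
            "intercept_proximodistal": self.slope_y.intercept,
            "variable_error_mediolateral": self.ve_x.mean_sd,
            "variable_error_proximodistal": self.ve_y.mean_sd,
        }


def exclude_outside(trials: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Drop trials whose click fell outside the board square.

    The board interior is [0, 1] x [0, 1] in Bookstein units, boundary
    inclusive: a click exactly on the edge is kept ("outside" excludes only
    strictly-outside points). Returns the kept trials and the fraction removed.
    """
    if len(trials) == 0:
        return trials.copy(), 0.0
    jx = trials["judged_x"].to_numpy(dtype=float)
    jy = trials["judged_y"].to_numpy(dtype=float)
    inside = (jx >= 0.0) & (jx <= 1.0) & (jy >= 0.0) & (jy <= 1.0)
    kept = trials.loc[inside].copy()
    return kept, 1.0 - len(kept) / len(trials)


def _single_value(trials: pd.DataFrame, column: str, default: str) -> str:
    if column in trials.columns:
        uniq = trials[column].unique()
        if len(uniq) == 1:
            return str(uniq[0])
    return default


def build_map(
    trials: pd.DataFrame,
    grid: StimulusGrid,
    participant: str | None = None,
    condition: str | None = None,
) -> PerceptualMap:
    """Per-location arithmetic mean of judged positions (after exclusion).

    Raises :class:`MissingLocationError` if any grid location has no valid
    trial — such a map has no homologous point and cannot enter Procrustes.
    """
    participant = participant or _single_value(trials, "participant", "pooled")
    condition = condition or _single_value(trials, "condition", "pooled")
    if len(trials) == 0:
        raise MissingLocationError("no trials at all")
    grouped = trials.groupby(["loc_row", "loc_col"])[["judged_x", "judged_y"]]
    means = grouped.mean()
    counts = grouped.size()
    coords = np.empty((grid.n_locations, 2))
    n_valid = np.empty(grid.n_locations, dtype=int)
    missing = []
    for r in range(1, grid.rows + 1):
        for c in range(1, grid.cols + 1):
            i = grid.index_of(r, c)
            if (r, c) in means.index:
                coords[i] = means.loc[(r, c)].to_numpy()
                n_valid[i] = counts.loc[(r, c)]
            else:
                missing.append(f"r{r}c{c}")
    if missing:
        raise MissingLocationError(
            f"no valid trials for location(s) {', '.join(missing)}"
        )
    return PerceptualMap(
        participant=participant,
        condition=condition,
        means=PointSet2D(coords, grid.labels),
        n_valid=n_valid,
    )


def _axis_regression(actual: np.ndarray, judged: np.ndarray, axis: Axis) -> AxisRegression:
    if actual.size < 2:
        raise DegenerateDataError(f"{axis}: need at least 2 trials")
    if np.ptp(actual) <= 0:
        raise DegenerateDataError(f"{axis}: actual coordinate has zero variance")
    fit = scipy.stats.linregress(actual, judged)
    return AxisRegression(
        axis=axis,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_trials=int(actual.size),
    )


def axis_slopes(
    trials: pd.DataFrame,
    on_location_means: bool = False,
) -> tuple[AxisRegression, AxisRegression]:
    """Localization slopes: OLS of judged on actual, separately per board axis.

    By default the regression is trial-level over all valid trials of the
    participant; ``on_location_means=True`` instead regresses the 36 per-location
    mean judgments on the actual locations (both conventions are defensible;
    the trial-level fit uses all data).

    Returns (medio-lateral fit, proximodistal fit).
    """
    data = trials
    if on_location_means:
        data = (
            trials.groupby(["loc_row", "loc_col"], as_index=False)
            [["actual_x", "actual_y", "judged_x", "judged_y"]]
            .mean()
        )
    reg_x = _axis_regression(
        data["actual_x"].to_numpy(dtype=float),
        data["judged_x"].to_numpy(dtype=float),
        "mediolateral",
    )
    reg_y = _axis_regression(
        data["actual_y"].to_numpy(dtype=float),
        data["judged_y"].to_numpy(dtype=float),
        "proximodistal",
    )
    return reg_x, reg_y


def variable_error(
    trials: pd.DataFrame, grid: StimulusGrid
) -> tuple[VariableError, VariableError]:
    """Per-location trial-to-trial SDs of judgments, separately per axis.

    Sample SDs use the n-1 denominator; ``mean_sd`` is the unweighted mean over
    the grid locations. Raises :class:`InsufficientRepetitionsError` if any
    location has fewer than 2 valid trials.

    Returns (medio-lateral, proximodistal).
    """
    grouped = trials.groupby(["loc_row", "loc_col"])[["judged_x", "judged_y"]]
    counts = grouped.size()
    sds = grouped.std(ddof=1)
    per_loc = np.empty((grid.n_locations, 2))
    problems = []
    for r in range(1, grid.rows + 1):
        for c in range(1, grid.cols + 1):
            i = grid.index_of(r, c)
            if (r, c) not in counts.index or counts.loc[(r, c)] < 2:
                problems.append(f"r{r}c{c}")
            else:
                per_loc[i] = sds.loc[(r, c)].to_numpy()
    if problems:
        raise InsufficientRepetitionsError(
            f"fewer than 2 valid trials at location(s) {', '.join(problems)}"
        )
    ve_x = VariableError("mediolateral", per_loc[:, 0].copy(), float(per_loc[:, 0].mean()))
    ve_y = VariableError("proximodistal", per_loc[:, 1].copy(), float(per_loc[:, 1].mean()))
    return ve_x, ve_y


def one_sample_t(values: Sequence[float], mu0: float = 0.0) -> GroupTest:
    """One-sample t-test of the mean against ``mu0``, with Cohen's d.

    t = (mean - mu0) / (SD / sqrt(n)); d = (mean - mu0) / SD; two-tailed p.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateDataError("need at least 2 values")
    sd = float(x.std(ddof=1))
    if sd <= 0:
        raise DegenerateDataError("sample standard deviation is zero")
    return one_sample_t_from_summary(float(x.mean()), sd, int(x.size), mu0)


def one_sample_t_from_summary(mean: float, sd: float, n: int, mu0: float = 0.0) -> GroupTest:
    """One-sample t-test computed from summary statistics (mean, SD, n)."""
    if n < 2:
        raise DegenerateDataError("need n >= 2")
    if not sd > 0:
        raise DegenerateDataError("standard deviation must be positive")
    t = (mean - mu0) / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * float(scipy.stats.t.sf(abs(t), df))
    return GroupTest(statistic=float(t), df=df, p=p,
                     effect=(mean - mu0) / sd, effect_kind="d", n=n)


def paired_t(a: Sequence[float], b: Sequence[float]) -> GroupTest:
    """Paired t-test (a vs b) with effect size dz = mean(a-b) / SD(a-b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    base = one_sample_t(a - b, 0.0)
    return GroupTest(statistic=base.statistic, df=base.df, p=base.p,
                     effect=base.effect, effect_kind="dz", n=base.n)


def pearson_r(a: Sequence[float], b: Sequence[float]) -> GroupTest:
    """Pearson correlation with df = n - 2 and two-tailed p via the t transform."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("samples must have equal length")
    if a.size < 3:
        raise DegenerateDataError("need at least 3 pairs")
    if a.std(ddof=1) <= 0 or b.std(ddof=1) <= 0:
        raise DegenerateDataError("correlation undefined for constant input")
    res = scipy.stats.pearsonr(a, b)
    return GroupTest(statistic=float(res.statistic), df=int(a.size - 2),
                     p=float(res.pvalue), effect=None, effect_kind=None, n=int(a.size))


def analyze_participant(
    trials: pd.DataFrame,
    grid: StimulusGrid,
    null_single: NullDistribution,
    allow_reflection: bool = True,
    participant: str | None = None,
    condition: str | None = None,
) -> ParticipantStats:
    """Full per-participant chain: exclusion, map, Procrustes + p, slopes, VE."""
    n_total = len(trials)
    kept, rate = exclude_outside(trials)
    pmap = build_map(kept, grid, participant=participant, condition=condition)
    result = procrustes_align(
        pmap.means, grid.bookstein_points, allow_reflection=allow_reflection
    )
    p = empirical_p(null_single, result.distance)
    reg_x, reg_y = axis_slopes(kept)
    ve_x, ve_y = variable_error(kept, grid)
    return ParticipantStats(
        participant=pmap.participant,
        condition=pmap.condition,
        n_trials=n_total,
        n_excluded=n_total - len(kept),
        exclusion_rate=rate,
        procrustes_distance=result.distance,
        procrustes_p=float(p),
        slope_x=reg_x,
        slope_y=reg_y,
        ve_x=ve_x,
        ve_y=ve_y,
    )


def analyze_cohort(
    trials: pd.DataFrame,
    grid: StimulusGrid,
    null_single: NullDistribution,
    allow_reflection: bool = True,
    condition: str | None = None,
) -> list[ParticipantStats]:
    """Run :func:`analyze_participant` for every participant in a trial table."""
    out = []
    for pid, sub in trials.groupby("participant", sort=True):
        out.append(
            analyze_participant(
                sub, grid, null_single,
                allow_reflection=allow_reflection,
                participant=str(pid), condition=condition,
            )
        )
    return out


def _described(values: np.ndarray, test: GroupTest | dict) -> dict:
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=1)) if values.size > 1 else None,
        "test": test.to_dict() if isinstance(test, GroupTest) else test,
    }


def _safe(testfn, *args) -> GroupTest | dict:
    try:
        return testfn(*args)
    except DegenerateDataError as exc:
        return {"error": str(exc)}


def analyze_group(
    stats: Sequence[ParticipantStats],
    null_group: NullDistribution | None = None,
) -> dict:
    """Group-level report over per-participant results.

    Covers: per-axis one-sample t of slopes against 0; paired t (and dz)
    comparing medio-lateral with proximodistal slopes; Pearson r between the
    axes' slopes; paired t on mean variable errors; and the grand-mean
    Procrustes distance with its group-null p-value. Degenerate statistics
    (e.g. a cohort of identical participants) are reported as errors in place,
    not raised.
    """
    if len(stats) < 2:
        raise DegenerateDataError("group analysis needs at least 2 participants")
    slopes_x = np.array([s.slope_x.slope for s in stats])
    slopes_y = np.array([s.slope_y.slope for s in stats])
    ve_x = np.array([s.ve_x.mean_sd for s in stats])
    ve_y = np.array([s.ve_y.mean_sd for s in stats])
    distances = np.array([s.procrustes_distance for s in stats])
    p_values = np.array([s.procrustes_p for s in stats])
    grand_mean = float(distances.mean())
    procrustes = {
        "grand_mean_distance": grand_mean,
        "per_participant_p": [float(p) for p in p_values],
        "n_below_p05": int(np.sum(p_values < 0.05)),
        "n_below_p01": int(np.sum(p_values < 0.01)),
    }
    if null_group is not None:
        procrustes["grand_mean_p"] = float(empirical_p(null_group, grand_mean))
    def as_dict(test: GroupTest | dict) -> dict:
        return test.to_dict() if isinstance(test, GroupTest) else test

    n_trials = int(sum(s.n_trials for s in stats))
    n_excluded = int(sum(s.n_excluded for s in stats))
    return {
        "n_participants": len(stats),
        "condition": stats[0].condition,
        "slope_mediolateral": _described(slopes_x, _safe(one_sample_t, slopes_x, 0.0)),
        "slope_proximodistal": _described(slopes_y, _safe(one_sample_t, slopes_y, 0.0)),
        "slope_anisotropy_paired": as_dict(_safe(paired_t, slopes_x, slopes_y)),
        "slope_axis_correlation": as_dict(_safe(pearson_r, slopes_x, slopes_y)),
        "variable_error_mediolateral": {"mean": float(ve_x.mean())},
        "variable_error_proximodistal": {"mean": float(ve_y.mean())},
        "variable_error_anisotropy_paired": as_dict(_safe(paired_t, ve_x, ve_y)),
        "procrustes": procrustes,
        "exclusion": {
            "n_trials": n_trials,
            "n_excluded": n_excluded,
            "rate": float(n_excluded / max(n_trials, 1)),
        },
    }
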
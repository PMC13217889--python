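"""Monte-Carlo null distributions for the Procrustes distance.

Chance-level localization is modeled as clicks falling uniformly over the board
square, independent of the stimulus. For each simulated participant the clicks
are averaged per location with the experiment's repetition count, and the
Procrustes distance of the resulting random map to the actual grid is recorded.
The study-scale null uses one million such simulations; the proportion of
simulated distances smaller than an observed distance is its one-tailed
empirical p-value (small distance = better-than-chance localization).

A group-level null for the grand-mean distance is built by resampling
``group_size`` values (with replacement) from the single-participant null and
recording their mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import DegenerateDataError
from .geometry import PointSet2D, StimulusGrid

__all__ = [
    "NullDistribution",
    "configuration_distances",
    "simulate_null_single",
    "simulate_null_group",
    "empirical_p",
]


@dataclass(frozen=True)
class NullDistribution:
    """A sorted Monte-Carlo sample of Procrustes distances, with provenance."""

    values: np.ndarray
    reps_per_location: int
    level: Literal["single", "group"]
    seed: int | None
    group_size: int | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("null distances must be finite and non-negative")
        if np.any(np.diff(values) < 0):
            values = np.sort(values)
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    @property
    def n_sims(self) -> int:
        return int(self.values.size)

    def percentile(self, q: float) -> float:
        return float(np.percentile(self.values, q))


def configuration_distances(
    maps: np.ndarray,
    target: StimulusGrid | PointSet2D | np.ndarray,
    allow_reflection: bool = True,
) -> np.ndarray:
    """Procrustes distances of a batch of configurations to a common target.

    ``maps`` has shape (m, n, 2). Uses the closed form for the 2x2 case: with
    A the centered cross-covariance matrix, the optimal similarity fit leaves
    residual sum of squares ``||Yc||^2 - (s1 +/- s2)^2 / ||Xc||^2`` where
    ``(s1 + s2)^2 = ||A||_F^2 + 2|det A|`` (reflection allowed) and
    ``(s1 + sign(det A) s2)^2 = ||A||_F^2 + 2 det A`` (rotation only).
    This avoids a per-simulation SVD and is cross-checked against the SVD
    path in the test suite.
    """
    if isinstance(target, StimulusGrid):
        Y = target.bookstein_points.coords
    elif isinstance(target, PointSet2D):
        Y = target.coords
    else:
        Y = np.asarray(target, dtype=float)
    maps = np.asarray(maps, dtype=float)
    if maps.ndim != 3 or maps.shape[1:] != Y.shape:
        raise ValueError(f"maps must have shape (m, {Y.shape[0]}, 2)")
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    norm_y2 = float(np.sum(Yc * Yc))
    Xc = maps - maps.mean(axis=1, keepdims=True)
    norm_x2 = np.einsum("mni,mni->m", Xc, Xc)
    A = np.einsum("mni,nj->mij", Xc, Yc)
    frob2 = np.einsum("mij,mij->m", A, A)
    det = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] * A[:, 1, 0]
    det_term = np.abs(det) if allow_reflection else det
    trace_eff2 = np.maximum(frob2 + 2.0 * det_term, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fitted = np.where(norm_x2 > 0, trace_eff2 / norm_x2, 0.0)
    ss = np.maximum(norm_y2 - fitted, 0.0)
    return np.sqrt(ss / n)


def _random_maps(
    rng: np.random.Generator, n_sims: int, n_locations: int, reps: int
) -> np.ndarray:
    clicks = rng.uniform(0.0, 1.0, size=(n_sims, n_locations, reps, 2))
    return clicks.mean(axis=2)


def simulate_null_single(
    grid: StimulusGrid,
    reps_per_location: int = 8,
    n_sims: int = 1_000_000,
    seed: int | None = None,
    allow_reflection: bool = True,
    chunk_size: int = 50_000,
) -> NullDistribution:
    """Null distribution of the Procrustes distance for one participant.

    Each simulation draws ``reps_per_location`` uniform clicks over the board
    square per stimulus location, averages them per location, and records the
    Procrustes distance of that random map to the actual grid. Deterministic
    given ``seed``.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if reps_per_location < 1:
        raise ValueError("reps_per_location must be >= 1")
    rng = np.random.default_rng(seed)
    target = grid.bookstein_points.coords
    out = np.empty(n_sims)
    done = 0
    while done < n_sims:
        m = min(chunk_size, n_sims - done)
        maps = _random_maps(rng, m, grid.n_locations, reps_per_location)
        out[done : done + m] = configuration_distances(
            maps, target, allow_reflection=allow_reflection
        )
        done += m
    out.sort()
    return NullDistribution(
        values=out,
        reps_per_location=reps_per_location,
        level="single",
        seed=seed,
    )


def simulate_null_group(
    single_null: NullDistribution,
    group_size: int,
    n_sims: int = 1_000_000,
    seed: int | None = None,
    chunk_size: int = 100_000,
) -> NullDistribution:
    """Null distribution of the grand-mean Procrustes distance of a cohort.

    Each simulation averages ``group_size`` values drawn with replacement from
    the single-participant null.
    """
    if single_null.n_sims == 0:
        raise DegenerateDataError("source null distribution is empty")
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    values = single_null.values
    out = np.empty(n_sims)
    done = 0
    while done < n_sims:
        m = min(chunk_size, n_sims - done)
        idx = rng.integers(0, values.size, size=(m, group_size))
        out[done : done + m] = values[idx].mean(axis=1)
        done += m
    out.sort()
    return NullDistribution(
        values=out,
        reps_per_location=single_null.reps_per_location,
        level="group",
        seed=seed,
        group_size=group_size,
    )


def empirical_p(null: NullDistribution, observed) -> float | np.ndarray:
    """One-tailed empirical p-value: proportion of null values strictly below ``observed``.

    Ties count as not smaller. Accepts a scalar or an array of observed values.
    """
    observed_arr = np.asarray(observed, dtype=float)
    if not np.all(np.isfinite(observed_arr)):
        raise ValueError("observed value must be finite")
    counts = np.searchsorted(null.values, observed_arr, side="left")
    p = counts / null.n_sims
    if np.isscalar(observed) or observed_arr.ndim == 0:
        return float(p)
    return p
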
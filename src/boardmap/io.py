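"""Trial-table I/O and null-distribution caching.

The interchange format for trial-level data is a plain CSV, one row per tap,
with the schema in :data:`TRIAL_COLUMNS`. Coordinates are Bookstein units by
default; files recorded in cm or pixels are registered on load given the two
board landmarks in the same units. Judged clicks may lie outside the board
square — exclusion is an analysis step, not a load step.

Null distributions are cached as plain CSV with a ``#``-prefixed metadata
header recording level, repetition count, simulation count, seed and group
size, so that million-simulation nulls are computed once and reused.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import SchemaError
from .geometry import StimulusGrid, bookstein_register, PointSet2D
from .nulls import NullDistribution

__all__ = [
    "TRIAL_COLUMNS",
    "read_trials",
    "write_trials",
    "validate_trials",
    "save_null",
    "load_null",
]

TRIAL_COLUMNS = [
    "participant",
    "experiment",
    "condition",
    "block",
    "trial_index",
    "loc_row",
    "loc_col",
    "actual_x",
    "actual_y",
    "judged_x",
    "judged_y",
]

_NUMERIC = ["block", "trial_index", "loc_row", "loc_col",
            "actual_x", "actual_y", "judged_x", "judged_y"]
_COORD_TOL = 1e-6


def _format_rows(rows: np.ndarray, limit: int = 10) -> str:
    # +2: one for the CSV header, one for 1-based line numbering
    lines = [str(int(r) + 2) for r in rows[:limit]]
    suffix = ", ..." if rows.size > limit else ""
    return ", ".join(lines) + suffix


def validate_trials(trials: pd.DataFrame, grid: StimulusGrid | None = None) -> pd.DataFrame:
    """Validate a trial table against the schema (and the grid, if given).

    Checks column presence, numeric parseability, actual coordinates within the
    board square, and consistency of (loc_row, loc_col) with (actual_x, actual_y).
    Returns the validated frame; raises :class:`SchemaError` naming offending
    CSV line numbers otherwise.
    """
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"missing columns: {', '.join(missing)}")
    out = trials.loc[:, TRIAL_COLUMNS].reset_index(drop=True).copy()
    for col in _NUMERIC:
        out[col] = pd.to_numeric(out[col], errors="coerce")
        bad = np.flatnonzero(out[col].isna().to_numpy())
        if bad.size:
            raise SchemaError(
                f"column '{col}' not numeric on line(s) {_format_rows(bad)}"
            )
    for col in ("block", "trial_index", "loc_row", "loc_col"):
        out[col] = out[col].astype(int)
    ax = out["actual_x"].to_numpy()
    ay = out["actual_y"].to_numpy()
    outside = np.flatnonzero((ax < -_COORD_TOL) | (ax > 1 + _COORD_TOL)
                             | (ay < -_COORD_TOL) | (ay > 1 + _COORD_TOL))
    if outside.size:
        raise SchemaError(
            f"actual coordinates outside the board on line(s) {_format_rows(outside)}"
        )
    if grid is not None:
        rows = out["loc_row"].to_numpy()
        cols = out["loc_col"].to_numpy()
        bad_idx = np.flatnonzero(
            (rows < 1) | (rows > grid.rows) | (cols < 1) | (cols > grid.cols)
        )
        if bad_idx.size:
            raise SchemaError(
                f"grid indices out of range on line(s) {_format_rows(bad_idx)}"
            )
        flat = (rows - 1) * grid.cols + (cols - 1)
        expected = grid.bookstein_points.coords[flat]
        mismatch = np.flatnonzero(
            (np.abs(ax - expected[:, 0]) > _COORD_TOL)
            | (np.abs(ay - expected[:, 1]) > _COORD_TOL)
        )
        if mismatch.size:
            raise SchemaError(
                "actual coordinates inconsistent with (loc_row, loc_col) "
                f"on line(s) {_format_rows(mismatch)}"
            )
    return out


def read_trials(
    path,
    grid: StimulusGrid | None = None,
    units: str = "bookstein",
    landmark_a: tuple[float, float] | None = None,
    landmark_b: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Read a trial CSV, registering coordinates into Bookstein units if needed.

    Parameters
    ----------
    units
        "bookstein" (default), or "cm" / "pixel"; the latter two require the
        two registration landmarks in the same units (for "cm", the board
        landmarks of ``grid`` are used when not given).
    """
    trials = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns: {', '.join(missing)}")
    if units not in ("bookstein", "cm", "pixel"):
        raise ValueError(f"unknown units {units!r}")
    if units != "bookstein":
        if landmark_a is None or landmark_b is None:
            if units == "cm" and grid is not None:
                landmark_a = grid.board.landmark_a
                landmark_b = grid.board.landmark_b
            else:
                raise SchemaError(
                    f"units={units!r} requires explicit landmark_a and landmark_b"
                )
        for prefix in ("actual", "judged"):
            pts = trials[[f"{prefix}_x", f"{prefix}_y"]].to_numpy(dtype=float)
            registered = bookstein_register(
                PointSet2D(pts, [str(i) for i in range(len(pts))]),
                landmark_a, landmark_b,
            ).coords
            trials[f"{prefix}_x"] = registered[:, 0]
            trials[f"{prefix}_y"] = registered[:, 1]
    try:
        return validate_trials(trials, grid)
    except SchemaError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table as CSV (losslessly round-trips through read_trials)."""
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise SchemaError(f"missing columns: {', '.join(missing)}")
    trials.loc[:, TRIAL_COLUMNS].to_csv(path, index=False, float_format="%.17g")


def save_null(null: NullDistribution, path) -> None:
    """Cache a null distribution as CSV with a metadata header."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# level={null.level}\n")
        fh.write(f"# n_sims={null.n_sims}\n")
        fh.write(f"# reps_per_location={null.reps_per_location}\n")
        fh.write(f"# seed={'' if null.seed is None else null.seed}\n")
        fh.write(f"# group_size={'' if null.group_size is None else null.group_size}\n")
        fh.write("value\n")
        np.savetxt(fh, null.values, fmt="%.17g")


def load_null(path) -> NullDistribution:
    """Load a null distribution cached by :func:`save_null`."""
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, skiprows=1, ndmin=1)
    for key in ("level", "n_sims", "reps_per_location"):
        if key not in meta:
            raise SchemaError(f"{path}: null cache missing metadata '{key}'")
    n_sims = int(meta["n_sims"])
    if values.size != n_sims:
        raise SchemaError(
            f"{path}: cache header says {n_sims} values but file holds {values.size}"
        )
    return NullDistribution(
        values=values,
        reps_per_location=int(meta["reps_per_location"]),
        level=meta["level"],  # type: ignore[arg-type]
        seed=int(meta["seed"]) if meta.get("seed") else None,
        group_size=int(meta["group_size"]) if meta.get("group_size") else None,
    )
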
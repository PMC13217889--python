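"""Generative model of the 2-D tactile localization experiment.

Makes the whole pipeline testable without the deposited raw data, and supports
parameter-recovery studies: a synthetic participant's judged click is a
linearly compressed version of the actual location plus anisotropic Gaussian
response noise, occasionally replaced by a lapse click.

Response model for a non-lapse trial::

    percept = center + (slope_x, slope_y) * (actual - center) + noise
    click   = percept clipped to the board square [0, 1]^2

``slope_x`` / ``slope_y`` are exactly the per-axis localization slopes the
analysis estimates (1 = veridical, 0 = no positional information); ``center``
is the convergence point of the compression; noise is independent Gaussian per
axis in Bookstein units. Clipping encodes that participants click on the
picture of the board, so ordinary responses never leave the square — consistent
with the very low observed outside-board rates (~0.2-0.4% of trials). With
probability ``lapse_rate`` the click is instead uniform over an extended
region (default [-0.1, 1.1]^2), so some lapses land outside the board and are
caught by the exclusion step while others are undetectable.

Study-scale defaults follow the two experiments this emulates: 20 participants,
6x6 grid, 8 repetitions per location (288 trials), medio-lateral slope
0.840 (between-participant SD 0.213), proximodistal slope 0.428 (SD 0.229),
response noise SDs 0.121 / 0.137 Bookstein units, lapse rate 0.0017.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BoardmapError
from .geometry import StimulusGrid, build_grid
from .io import TRIAL_COLUMNS

__all__ = [
    "ParticipantModel",
    "ExperimentDesign",
    "experiment1_design",
    "experiment2_design",
    "generate_trials",
    "generate_cohort",
    "draw_cohort_models",
    "experiment1_cohort",
    "uniform_responder",
]

# Printed group-level parameter scales for the two experiments (Bookstein units).
EXP1_SLOPE_ML = (0.840, 0.213)
EXP1_SLOPE_PD = (0.428, 0.229)
EXP1_NOISE_ML = 0.121
EXP1_NOISE_PD = 0.137
EXP1_LAPSE = 0.0017
EXP2_LAPSE = 0.0044


@dataclass(frozen=True)
class ParticipantModel:
    """Response-model parameters for one synthetic participant.

    ``slope_*`` are compression factors toward ``center`` (unitless),
    ``noise_sd_*`` Gaussian response noise per axis (Bookstein units),
    ``lapse_rate`` the probability of a uniform click over ``lapse_region``
    (a (lo, hi) interval applied to both axes; may extend beyond the board).
    """

    slope_x: float = EXP1_SLOPE_ML[0]
    slope_y: float = EXP1_SLOPE_PD[0]
    center: tuple[float, float] = (0.5, 0.5)
    noise_sd_x: float = EXP1_NOISE_ML
    noise_sd_y: float = EXP1_NOISE_PD
    lapse_rate: float = EXP1_LAPSE
    lapse_region: tuple[float, float] = (-0.1, 1.1)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd_x < 0 or self.noise_sd_y < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must lie in [0, 1]")
        if not self.lapse_region[1] > self.lapse_region[0]:
            raise ValueError("lapse_region must be a non-empty interval")


def uniform_responder(seed: int | None = None) -> ParticipantModel:
    """A chance-level participant: every click uniform over the board square."""
    return ParticipantModel(
        slope_x=0.0, slope_y=0.0, noise_sd_x=0.0, noise_sd_y=0.0,
        lapse_rate=1.0, lapse_region=(0.0, 1.0), seed=seed,
    )


@dataclass(frozen=True)
class ExperimentDesign:
    """Grid, per-condition repetition counts and cohort size of an experiment."""

    grid: StimulusGrid
    conditions: tuple[tuple[str, int], ...] = (("none", 8),)
    n_participants: int = 20
    experiment: str = "exp1"

    def __post_init__(self) -> None:
        conditions = tuple((str(lb), int(r)) for lb, r in dict(self.conditions).items())
        if not conditions or any(r < 1 for _, r in conditions):
            raise ValueError("each condition needs at least 1 repetition")
        object.__setattr__(self, "conditions", conditions)

    @property
    def trials_per_participant(self) -> int:
        return self.grid.n_locations * sum(r for _, r in self.conditions)


def experiment1_design(
    grid: StimulusGrid | None = None, n_participants: int = 20
) -> ExperimentDesign:
    """Single-posture design: 8 randomized sweeps of the 36 locations (288 trials)."""
    return ExperimentDesign(
        grid=grid if grid is not None else build_grid(),
        conditions=(("none", 8),),
        n_participants=n_participants,
        experiment="exp1",
    )


def experiment2_design(
    grid: StimulusGrid | None = None, n_participants: int = 18
) -> ExperimentDesign:
    """Two-posture design: 4 sweeps per posture, posture order ABBA (288 trials)."""
    return ExperimentDesign(
        grid=grid if grid is not None else build_grid(),
        conditions=(("normal", 4), ("rotated", 4)),
        n_participants=n_participants,
        experiment="exp2",
    )


def _block_plan(design: ExperimentDesign) -> list[str]:
    """Condition label of each block (one block = one randomized sweep).

    Single condition: blocks 1..reps. Multiple conditions: ABBA-style
    alternation (forward, reversed, forward, ...) until all repetitions are
    scheduled, mirroring counterbalanced posture blocks.
    """
    remaining = {label: reps for label, reps in design.conditions}
    order = [label for label, _ in design.conditions]
    plan: list[str] = []
    forward = True
    while any(remaining.values()):
        for label in order if forward else reversed(order):
            if remaining[label] > 0:
                plan.append(label)
                remaining[label] -= 1
        forward = not forward
    return plan


def generate_trials(
    model: ParticipantModel | Mapping[str, ParticipantModel],
    design: ExperimentDesign,
    participant: str = "P01",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate one participant's full session as a trial table.

    ``model`` is a single :class:`ParticipantModel`, or a mapping from condition
    label to model when the response parameters differ between conditions (as
    between postures). Each block presents every grid location once in random
    order. Reproducible given the model seed or an explicit ``rng``.
    """
    if rng is None:
        seed = model.seed if isinstance(model, ParticipantModel) else None
        rng = np.random.default_rng(seed)
    if isinstance(model, ParticipantModel):
        models: Mapping[str, ParticipantModel] = {
            label: model for label, _ in design.conditions
        }
    else:
        models = dict(model)
        missing = [lb for lb, _ in design.conditions if lb not in models]
        if missing:
            raise BoardmapError(f"no model for condition(s) {', '.join(missing)}")

    grid = design.grid
    coords = grid.bookstein_points.coords
    n_loc = grid.n_locations
    loc_rows = np.repeat(np.arange(1, grid.rows + 1), grid.cols)
    loc_cols = np.tile(np.arange(1, grid.cols + 1), grid.rows)

    frames = []
    trial_counter = 0
    for block_no, label in enumerate(_block_plan(design), start=1):
        m = models[label]
        perm = rng.permutation(n_loc)
        actual = coords[perm]
        center = np.asarray(m.center, dtype=float)
        slope = np.array([m.slope_x, m.slope_y])
        noise = rng.normal(0.0, [m.noise_sd_x, m.noise_sd_y], size=(n_loc, 2))
        percept = center + slope * (actual - center) + noise
        judged = np.clip(percept, 0.0, 1.0)
        lapse = rng.random(n_loc) < m.lapse_rate
        if lapse.any():
            lo, hi = m.lapse_region
            judged[lapse] = rng.uniform(lo, hi, size=(int(lapse.sum()), 2))
        frames.append(pd.DataFrame({
            "participant": participant,
            "experiment": design.experiment,
            "condition": label,
            "block": block_no,
            "trial_index": np.arange(trial_counter + 1, trial_counter + n_loc + 1),
            "loc_row": loc_rows[perm],
            "loc_col": loc_cols[perm],
            "actual_x": actual[:, 0],
            "actual_y": actual[:, 1],
            "judged_x": judged[:, 0],
            "judged_y": judged[:, 1],
        }))
        trial_counter += n_loc
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def generate_cohort(
    models: Sequence[ParticipantModel | Mapping[str, ParticipantModel]],
    design: ExperimentDesign,
    seed: int | None = 0,
    participant_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate a cohort; per-participant RNG streams derive from the cohort seed.

    Raises on duplicate participant identifiers.
    """
    n = len(models)
    if participant_ids is None:
        participant_ids = [f"P{i + 1:02d}" for i in range(n)]
    if len(set(participant_ids)) != len(participant_ids):
        raise BoardmapError("duplicate participant identifiers")
    if len(participant_ids) != n:
        raise BoardmapError("one identifier per model required")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = ss.spawn(n)
    frames = [
        generate_trials(model, design, participant=pid, rng=np.random.default_rng(ss))
        for model, pid, ss in zip(models, participant_ids, streams)
    ]
    return pd.concat(frames, ignore_index=True)


def draw_cohort_models(
    n_participants: int,
    rng: np.random.Generator | int | None,
    slope_x: tuple[float, float] = EXP1_SLOPE_ML,
    slope_y: tuple[float, float] = EXP1_SLOPE_PD,
    noise_sd_x: float = EXP1_NOISE_ML,
    noise_sd_y: float = EXP1_NOISE_PD,
    lapse_rate: float = EXP1_LAPSE,
) -> list[ParticipantModel]:
    """Draw per-participant models with Normal between-participant slope spread.

    Slopes are drawn untruncated (overshoot beyond 1 and occasional failure
    below 0 are meaningful); noise SDs and lapse rate are common to the cohort.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sx = rng.normal(slope_x[0], slope_x[1], size=n_participants)
    sy = rng.normal(slope_y[0], slope_y[1], size=n_participants)
    return [
        ParticipantModel(
            slope_x=float(sx[i]), slope_y=float(sy[i]),
            noise_sd_x=noise_sd_x, noise_sd_y=noise_sd_y,
            lapse_rate=lapse_rate,
        )
        for i in range(n_participants)
    ]


def experiment1_cohort(
    seed: int | None = 0,
    n_participants: int = 20,
    grid: StimulusGrid | None = None,
) -> tuple[pd.DataFrame, ExperimentDesign]:
    """Convenience: a study-scale single-posture cohort at the printed parameters."""
    design = experiment1_design(grid=grid, n_participants=n_participants)
    ss = np.random.SeedSequence(seed)
    model_seed, cohort_seed = ss.spawn(2)
    models = draw_cohort_models(n_participants, np.random.default_rng(model_seed))
    trials = generate_cohort(models, design, seed=cohort_seed)
    return trials, design
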
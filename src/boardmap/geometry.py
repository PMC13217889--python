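"""Board geometry, Bookstein shape coordinates, and Procrustes superimposition.

The experiment taps locations on a square board held in the hand; judgments are
clicks on a same-sized picture of the board. All analysis happens in Bookstein
two-point shape coordinates: the bottom-left and bottom-right corners of the
board are mapped to (0, 0) and (1, 0), which removes position, orientation and
size, and fixes x as the medio-lateral axis and y as the proximodistal axis of
the held board.

A participant's perceptual map (per-location mean judged position) is compared
with the actual stimulus layout by full similarity Procrustes superimposition:
the least-squares translation, rotation, uniform scaling (and optionally
reflection) of one configuration onto the other. The residual mismatch is
summarized as the Procrustes distance, defined here as the root mean square of
the distances between homologous points after alignment — 0 when the two
configurations have identical shape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import (
    AlignmentError,
    DegenerateConfigurationError,
    GridGeometryError,
    InvalidLandmarkError,
)

__all__ = [
    "PointSet2D",
    "BoardSpec",
    "StimulusGrid",
    "ProcrustesResult",
    "bookstein_register",
    "build_grid",
    "procrustes_align",
    "procrustes_distance",
]

_COINCIDENT_TOL = 1e-12


@dataclass(frozen=True)
class PointSet2D:
    """An ordered, labelled set of 2-D points.

    Parameters
    ----------
    coords
        Array of shape (n, 2); finite values required.
    labels
        One identifier per point, aligned with ``coords`` rows.
    """

    coords: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError(f"coords must have shape (n, 2), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords must be finite")
        labels = tuple(str(lb) for lb in self.labels)
        if len(labels) != coords.shape[0]:
            raise ValueError(
                f"{len(labels)} labels for {coords.shape[0]} points"
            )
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return self.coords.shape[0]

    def reordered(self, labels: Sequence[str]) -> "PointSet2D":
        """Return a copy with rows re-ordered to follow ``labels``."""
        index = {lb: i for i, lb in enumerate(self.labels)}
        try:
            order = [index[str(lb)] for lb in labels]
        except KeyError as exc:
            raise AlignmentError(f"label {exc} not present in point set") from exc
        return PointSet2D(self.coords[order], tuple(str(lb) for lb in labels))


@dataclass(frozen=True)
class BoardSpec:
    """A square board with two registration landmarks on its bottom edge.

    ``landmark_a`` / ``landmark_b`` default to the bottom-left and bottom-right
    corners in board-fixed cm coordinates (origin at the bottom-left corner).
    """

    side_cm: float = 23.0
    landmark_a: tuple[float, float] | None = None
    landmark_b: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (self.side_cm > 0):
            raise ValueError("side_cm must be positive")
        a = (0.0, 0.0) if self.landmark_a is None else tuple(map(float, self.landmark_a))
        b = (float(self.side_cm), 0.0) if self.landmark_b is None else tuple(map(float, self.landmark_b))
        if math.hypot(b[0] - a[0], b[1] - a[1]) <= _COINCIDENT_TOL:
            raise InvalidLandmarkError("board landmarks coincide")
        object.__setattr__(self, "landmark_a", a)
        object.__setattr__(self, "landmark_b", b)


def bookstein_register(
    points: PointSet2D,
    landmark_a: tuple[float, float],
    landmark_b: tuple[float, float],
) -> PointSet2D:
    """Map ``points`` to Bookstein two-point shape coordinates.

    A similarity transform (translation + rotation + uniform scaling, no
    reflection) sends ``landmark_a`` to (0, 0) and ``landmark_b`` to (1, 0);
    the same transform is applied to every point, so the relative configuration
    is preserved exactly.

    Raises
    ------
    InvalidLandmarkError
        If the two landmarks coincide.
    """
    a = complex(*map(float, landmark_a))
    b = complex(*map(float, landmark_b))
    if abs(b - a) <= _COINCIDENT_TOL:
        raise InvalidLandmarkError("registration landmarks coincide")
    z = points.coords[:, 0] + 1j * points.coords[:, 1]
    w = (z - a) / (b - a)
    return PointSet2D(np.column_stack([w.real, w.imag]), points.labels)


def grid_label(row: int, col: int) -> str:
    """Canonical label of the stimulus location in grid row ``row`` / column ``col``.

    Rows count 1..n_rows from the bottom (proximal) edge upward; columns count
    1..n_cols from left to right.
    """
    return f"r{int(row)}c{int(col)}"


@dataclass(frozen=True)
class StimulusGrid:
    """The actual stimulus layout: a rows x cols lattice of marks on the board.

    ``board_points`` holds the mark positions in board-fixed cm; ``bookstein_points``
    holds the same marks after two-point registration with the board's landmarks.
    Points are ordered row-major from the bottom-left mark: (row 1, col 1),
    (row 1, col 2), ...
    """

    rows: int
    cols: int
    spacing_cm: float
    board: BoardSpec
    board_points: PointSet2D = field(repr=False)
    bookstein_points: PointSet2D = field(repr=False)

    @property
    def n_locations(self) -> int:
        return self.rows * self.cols

    @property
    def labels(self) -> tuple[str, ...]:
        return self.bookstein_points.labels

    def index_of(self, row: int, col: int) -> int:
        if not (1 <= row <= self.rows and 1 <= col <= self.cols):
            raise KeyError(f"no grid location r{row}c{col}")
        return (row - 1) * self.cols + (col - 1)


def build_grid(
    board: BoardSpec | None = None,
    rows: int = 6,
    cols: int = 6,
    spacing_cm: float = 3.3,
    slack: float = 0.02,
) -> StimulusGrid:
    """Construct the stimulus grid, centered on the board with equal outer margins.

    The study's nominal geometry (marks 3.3 cm apart, with the outer marks also
    3.3 cm from the board edge, on a 23 cm board) over-fills the board by 1 mm
    (7 x 3.3 = 23.1 cm); the grid is therefore placed centered, absorbing the
    discrepancy into the margins, and a nominal-footprint mismatch beyond
    ``slack`` (default 2%) is rejected as a geometry error.

    Raises
    ------
    GridGeometryError
        If the marks do not fit on the board, or the nominal footprint
        ``(n + 1) * spacing`` deviates from the board side by more than ``slack``.
    """
    board = board if board is not None else BoardSpec()
    if rows < 2 or cols < 2:
        raise GridGeometryError("grid needs at least 2 rows and 2 columns")
    if spacing_cm <= 0:
        raise GridGeometryError("spacing must be positive")
    side = board.side_cm
    for n_axis in (rows, cols):
        if (n_axis - 1) * spacing_cm >= side:
            raise GridGeometryError(
                f"{n_axis} marks spaced {spacing_cm} cm do not fit on a {side} cm board"
            )
        nominal = (n_axis + 1) * spacing_cm
        if abs(nominal - side) > slack * side:
            raise GridGeometryError(
                f"nominal footprint {nominal:.2f} cm deviates from the {side} cm board "
                f"by more than {slack:.0%}"
            )
    margin_x = (side - (cols - 1) * spacing_cm) / 2.0
    margin_y = (side - (rows - 1) * spacing_cm) / 2.0
    xs = margin_x + spacing_cm * np.arange(cols)
    ys = margin_y + spacing_cm * np.arange(rows)
    coords = np.array([(x, y) for y in ys for x in xs])
    labels = tuple(
        grid_label(r, c) for r in range(1, rows + 1) for c in range(1, cols + 1)
    )
    board_points = PointSet2D(coords, labels)
    bookstein_points = bookstein_register(board_points, board.landmark_a, board.landmark_b)
    return StimulusGrid(
        rows=rows,
        cols=cols,
        spacing_cm=float(spacing_cm),
        board=board,
        board_points=board_points,
        bookstein_points=bookstein_points,
    )


@dataclass(frozen=True)
class ProcrustesResult:
    """Outcome of a similarity Procrustes superimposition of source onto target.

    ``distance`` is the RMS of homologous point-pair distances after alignment,
    in target units. ``aligned`` is the transformed source; the transform is
    ``aligned = scale * source @ R + translation`` with ``R`` the (row-acting)
    orthogonal matrix, ``reflected`` indicating det(R) < 0.
    """

    distance: float
    scale: float
    rotation_deg: float
    translation: tuple[float, float]
    reflected: bool
    aligned: PointSet2D


def _match_to_target(source: PointSet2D, target: PointSet2D) -> PointSet2D:
    if len(source) != len(target):
        raise AlignmentError(
            f"point counts differ: {len(source)} vs {len(target)}"
        )
    if source.labels == target.labels:
        return source
    if sorted(source.labels) != sorted(target.labels):
        raise AlignmentError("source and target labels do not match")
    return source.reordered(target.labels)


def procrustes_align(
    source: PointSet2D,
    target: PointSet2D,
    allow_reflection: bool = True,
) -> ProcrustesResult:
    """Least-squares similarity superimposition of ``source`` onto ``target``.

    Minimizes the sum of squared homologous-point distances over translation,
    rotation, uniform scale and (if ``allow_reflection``) reflection, via the
    singular value decomposition of the centered cross-covariance matrix.
    Points are matched by label; the source is re-ordered if necessary.

    Raises
    ------
    AlignmentError
        Mismatched point counts or labels.
    DegenerateConfigurationError
        All source (or target) points coincide.
    """
    source = _match_to_target(source, target)
    if len(source) < 2:
        raise DegenerateConfigurationError("need at least 2 points to align")
    X = source.coords
    Y = target.coords
    mx = X.mean(axis=0)
    my = Y.mean(axis=0)
    Xc = X - mx
    Yc = Y - my
    norm_x2 = float(np.sum(Xc * Xc))
    norm_y2 = float(np.sum(Yc * Yc))
    if norm_x2 <= _COINCIDENT_TOL:
        raise DegenerateConfigurationError("all source points coincide")
    if norm_y2 <= _COINCIDENT_TOL:
        raise DegenerateConfigurationError("all target points coincide")

    A = Xc.T @ Yc
    U, svals, Vt = np.linalg.svd(A)
    R = U @ Vt
    trace = float(svals.sum())
    if np.linalg.det(R) < 0 and not allow_reflection:
        D = np.diag([1.0, -1.0])
        R = U @ D @ Vt
        trace = float(svals[0] - svals[1])
    scale = max(trace, 0.0) / norm_x2
    aligned_coords = scale * (Xc @ R) + my
    residual = aligned_coords - Y
    distance = float(np.sqrt(np.mean(np.sum(residual * residual, axis=1))))
    # R acts on row vectors; the equivalent column-action matrix is R.T.
    M = R.T
    rotation_deg = float(np.degrees(np.arctan2(M[1, 0], M[0, 0])))
    translation = my - scale * (mx @ R)
    return ProcrustesResult(
        distance=distance,
        scale=float(scale),
        rotation_deg=rotation_deg,
        translation=(float(translation[0]), float(translation[1])),
        reflected=bool(np.linalg.det(R) < 0),
        aligned=PointSet2D(aligned_coords, target.labels),
    )


def procrustes_distance(
    source,
    grid: StimulusGrid | PointSet2D,
    allow_reflection: bool = True,
) -> float:
    """Procrustes distance between a perceptual map (or point set) and the grid.

    Convenience wrapper: aligns the judged configuration onto the actual
    stimulus layout and returns the RMS residual in Bookstein units.
    """
    target = grid.bookstein_points if isinstance(grid, StimulusGrid) else grid
    points = getattr(source, "means", source)
    return procrustes_align(points, target, allow_reflection=allow_reflection).distance
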
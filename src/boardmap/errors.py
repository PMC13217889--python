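"""Exception hierarchy for boardmap.

Every failure mode the analysis contracts define maps to one of these, so callers
can distinguish bad geometry from bad data from degenerate statistics.
"""


class BoardmapError(Exception):
    """Base class for all boardmap errors."""


class InvalidLandmarkError(BoardmapError):
    """Two-point registration landmarks coincide (or nearly so)."""


class GridGeometryError(BoardmapError):
    """Requested stimulus grid does not fit on the board."""


class AlignmentError(BoardmapError):
    """Point configurations cannot be superimposed (count or label mismatch)."""


class DegenerateConfigurationError(BoardmapError):
    """A point configuration carries no shape information (all points coincide)."""


class DegenerateDataError(BoardmapError):
    """A statistic is undefined for the sample (zero variance, constant input)."""


class MissingLocationError(BoardmapError):
    """A stimulus location has no valid trials, so no perceptual map entry exists."""


class InsufficientRepetitionsError(BoardmapError):
    """A per-location dispersion is requested with fewer than 2 valid trials."""


class SchemaError(BoardmapError):
    """A trial table fails schema or consistency validation."""
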
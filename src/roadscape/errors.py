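"""Exception hierarchy for roadscape.

All errors raised by the library derive from :class:`RoadscapeError` so
callers (and the CLI) can catch pipeline failures uniformly.
"""


class RoadscapeError(Exception):
    """Base class for all roadscape errors."""


class ShapeError(RoadscapeError):
    """Surfaces or grids with incompatible dimensions were combined."""


class ValidationError(RoadscapeError):
    """An input value violates a documented precondition (negative stock,
    un-rescaled surface, unknown ecoregion id, bad parameter, ...)."""


class ParameterError(ValidationError):
    """Invalid generator or pipeline parameters."""


class DegenerateInputError(RoadscapeError):
    """Structurally valid input that the operation cannot act on
    (too few valid cells, empty buffer, road outside the grid)."""


class FormatError(RoadscapeError):
    """A file could not be parsed in the expected format."""
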
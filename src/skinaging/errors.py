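"""Exception hierarchy for the skinaging pipeline.

The CLI maps :class:`ConfigurationError` to exit code 2 and
:class:`DataError` (and subclasses) to exit code 3.
"""


class SkinAgingError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SkinAgingError):
    """Invalid configuration: bad thresholds, scales, or spec fields."""


class DataError(SkinAgingError):
    """Invalid or degenerate input data."""


class PlacementError(DataError):
    """Requested synthetic objects could not be placed disjointly.

    Carries the number of objects successfully placed before giving up.
    """

    def __init__(self, placed: int, requested: int, message: str | None = None):
        self.placed = placed
        self.requested = requested
        super().__init__(
            message
            or f"placed only {placed} of {requested} requested objects "
            "before exhausting placement attempts"
        )


class UndefinedReversalError(DataError):
    """Reversal years are undefined: the subject did not age on this score."""


class PipelineStageError(SkinAgingError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}': {original}")
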
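"""Exception hierarchy.

Every error segscore raises deliberately derives from :class:`SegscoreError`,
so callers (and the CLI) can distinguish data problems from bugs.
"""


class SegscoreError(Exception):
    """Base class for all segscore errors."""


class ShapeMismatchError(SegscoreError):
    """Ground-truth and prediction masks do not share dimensions."""


class FormatError(SegscoreError):
    """An input file is not a supported label-image / submission format."""


class RleOverlapError(SegscoreError):
    """Two run-length-encoded instances claim the same pixel."""


class RleBoundsError(SegscoreError):
    """A run-length record extends past the image area."""


class BoundsError(SegscoreError):
    """A detection point lies outside the image bounds."""


class SpecParseError(SegscoreError, ValueError):
    """A metric-notation string could not be parsed."""


class MissingConfidenceError(SegscoreError):
    """A curve-based metric was requested but a prediction has no confidence."""


class EmptyDatasetError(SegscoreError):
    """An averaging operation was asked to average over nothing."""


class InsufficientDataError(SegscoreError):
    """Fewer submissions than a correlation analysis needs."""


class CapacityError(SegscoreError):
    """Scene generation could not place the requested number of objects."""

    def __init__(self, requested: int, achieved: int):
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could not place {requested} objects; {achieved} fit with the "
            f"given size range and minimum gap"
        )


class ValidationError(SegscoreError):
    """A configuration field has an invalid value."""
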
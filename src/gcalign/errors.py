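"""Exception hierarchy for gcalign."""


class GcAlignError(Exception):
    """Base class for all gcalign errors."""


class FormatError(GcAlignError):
    """A peak-table file does not conform to the expected layout."""


class EmptyInputError(FormatError):
    """An input table contains no usable peak rows."""


class SpectrumParseError(FormatError):
    """A spectrum string could not be parsed."""


class InvalidSpectrumError(GcAlignError):
    """A spectrum violates its invariants (e.g. no positive intensity)."""


class ParameterError(GcAlignError, ValueError):
    """A user-supplied parameter is outside its valid range."""


class DegenerateDataError(GcAlignError):
    """The data carry no information for the requested estimation."""


class InsufficientDataError(GcAlignError):
    """Too few observations to fit the model."""


class NotFittedError(GcAlignError):
    """A model was used before being fitted."""


class AlignmentError(GcAlignError):
    """Base class for landmark/RT-adjustment failures."""


class NoLandmarksError(AlignmentError):
    """No peak chain spans all runs; alignment is impossible."""


class InsufficientLandmarksError(AlignmentError):
    """Fewer than two distinct landmark knots in a dimension."""


class CrossingLandmarksError(AlignmentError):
    """Representative landmark RTs are not monotone in target RT order."""

    def __init__(self, message, knots=None):
        super().__init__(message)
        self.knots = knots
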
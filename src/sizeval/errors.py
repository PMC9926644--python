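"""Typed exceptions raised by sizeval components.

Every error derives from :class:`SizevalError` so callers can catch the
package's failures without masking unrelated bugs.
"""


class SizevalError(Exception):
    """Base class for all sizeval errors."""


class TwoClassViolationError(SizevalError):
    """The labels do not contain exactly two classes with >= 2 samples each."""


class DegenerateVarianceError(SizevalError):
    """A pooled standard deviation is zero, so Cohen's d is undefined."""


class InvalidRangeError(SizevalError):
    """An effect-size range or fraction parameter is outside its domain."""


class InsufficientDataError(SizevalError):
    """Fewer balanced samples are available than the schedule floor requires."""


class ClassTooSmallError(SizevalError):
    """A class has too few samples for the requested balanced subsample."""


class DegenerateFoldError(SizevalError):
    """A cross-validation training fold contains a single class."""


class EmptyGroupError(SizevalError):
    """An aggregation group has fewer repetitions than required."""


class MissingArtifactError(SizevalError):
    """A pipeline output bundle is missing a required artifact."""
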
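"""Exception hierarchy for glyvar.

All exceptions derive from :class:`GlyvarError` so callers can catch
library failures with a single ``except`` clause while still
distinguishing bad input files from bad values or too-short traces.
"""


class GlyvarError(Exception):
    """Base class for all glyvar errors."""


class InputFormatError(GlyvarError):
    """A file could not be parsed as the expected CSV dialect."""


class ValidationError(GlyvarError):
    """A value or parameter violates an invariant (bad unit tag,
    non-increasing timestamps, negative threshold, ...)."""


class InsufficientDataError(GlyvarError):
    """Too few samples (or too few within-run segments / lagged pairs)
    to compute the requested quantity."""


class UnitError(ValidationError):
    """Glucose unit is not acceptable for the requested computation."""
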
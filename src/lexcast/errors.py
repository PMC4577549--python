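"""Typed exception hierarchy.

Every error raised by lexcast derives from :class:`LexcastError` so that
pipeline harnesses can catch model failures without masking programming
errors, and record them as typed status rows.
"""


class LexcastError(Exception):
    """Base class for all lexcast errors."""


class ParseError(LexcastError):
    """Malformed input text (carries a line number where possible)."""


class MissingDataError(LexcastError):
    """A required (year, age) cell is missing inside the requested window."""


class ContiguityError(LexcastError):
    """Year or age axis is not contiguous."""


class OutOfRangeError(LexcastError):
    """Requested subset lies outside the available data."""


class AlignmentError(LexcastError):
    """Two surfaces do not share the required age/year grid."""


class DomainError(LexcastError):
    """Numeric input outside the mathematical domain of an operation."""


class InsufficientDataError(LexcastError):
    """Not enough years (or ages) of data for the requested operation."""


class DegenerateFitError(LexcastError):
    """Model fit is degenerate (e.g. rank-0 centered log-rate matrix)."""


class DegenerateDataError(LexcastError):
    """Data degenerate for the requested operation (e.g. all-zero deaths)."""


class ConfigError(LexcastError):
    """Missing or invalid configuration key; message names the key."""


class TableLookupError(LexcastError):
    """Missing key in a quantile table lookup."""
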
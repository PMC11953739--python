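"""Exception hierarchy for quadassay.

All package-specific failures derive from :class:`QuadAssayError` so callers
can catch one base class at CLI boundaries.
"""


class QuadAssayError(Exception):
    """Base class for all quadassay errors."""


class SchemaError(QuadAssayError):
    """An input table is missing a required column or has a bad header."""


class CountValidationError(QuadAssayError):
    """A data row holds an invalid value (negative/non-integer count, bad enum).

    Parameters
    ----------
    message : str
        Human-readable description.
    row : int, optional
        1-based data-row index (header excluded) of the offending row.
    """

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class UndefinedInputError(QuadAssayError):
    """A metric was requested for an input on which it is undefined (e.g. zero total)."""


class InsufficientDataError(QuadAssayError):
    """Too few values or groups to compute the requested statistic."""


class InfiniteEffectError(QuadAssayError):
    """Effect size requested where both group standard deviations are zero but means differ."""


class ConfigError(QuadAssayError):
    """A configuration file or value is invalid; the message names the key."""
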
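"""Exception hierarchy.

Every error raised by this package derives from :class:`AlongTractError`,
split by failure kind so callers (and the CLI exit-code mapping) can
distinguish configuration mistakes, malformed inputs, contract violations
and numerical failures.
"""


class AlongTractError(Exception):
    """Base class for all package errors."""


class ConfigError(AlongTractError):
    """An invalid configuration value; the message names the field."""


class FormatError(AlongTractError):
    """A structurally malformed input table (missing column, duplicates)."""


class ValidationError(AlongTractError):
    """Structurally well-formed data that violates a semantic invariant."""


class ParameterError(AlongTractError):
    """An out-of-range argument to an operation."""


class ContractError(AlongTractError):
    """A violated call contract between pipeline components."""


class RankError(AlongTractError):
    """A rank-deficient design matrix or basis."""


class ShapeError(AlongTractError):
    """Mismatched dimensions between tables that must align."""


class InsufficientDataError(AlongTractError):
    """Too few observations to compute the requested statistic."""


class GroupingError(AlongTractError):
    """A grouping rule produced an empty or degenerate group."""


class NumericalError(AlongTractError):
    """A numerically singular or otherwise unstable computation."""


class GenerationError(AlongTractError):
    """The synthetic generator cannot satisfy its geometric constraints."""
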
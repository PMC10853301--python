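"""Exception hierarchy for basinrank.

All errors raised by the package derive from :class:`BasinRankError`, so
callers (and the CLI) can distinguish bad inputs from genuine bugs.
"""


class BasinRankError(Exception):
    """Base class for all basinrank errors."""


class SchemaError(BasinRankError):
    """A required column is missing or a table has the wrong shape."""


class TableValidationError(BasinRankError):
    """A cell value violates a domain invariant (names row and field)."""


class ReferentialError(BasinRankError):
    """A subbasin references a basin_id that does not exist."""


class ConfigError(BasinRankError):
    """A ranking configuration violates its invariants."""


class DomainError(BasinRankError):
    """An operation received a value outside its mathematical domain."""
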
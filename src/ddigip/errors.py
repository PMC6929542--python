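"""Named exceptions raised by the ddigip package.

Every error that a caller may reasonably want to catch has its own class;
the CLI maps each family to a distinct exit code.
"""


class DdigipError(Exception):
    """Base class for all package errors."""


class DataFormatError(DdigipError):
    """Malformed input data (files or in-memory tables)."""


class SelfInteractionError(DataFormatError):
    """An edge list names a drug interacting with itself."""


class UnknownDrugError(DataFormatError):
    """An identifier does not exist in the supplied drug index."""


class DuplicateDrugError(DataFormatError):
    """A drug identifier occurs more than once where uniqueness is required."""


class NonBinaryValueError(DataFormatError):
    """A feature-table cell is not 0 or 1."""


class EmptyTableError(DataFormatError):
    """A table contains no data rows."""


class DegenerateNetworkError(DdigipError):
    """The interaction matrix is all zero: the GIP bandwidth is undefined."""


class InvalidParameterError(DdigipError):
    """A parameter violates its precondition (e.g. sigma <= 0)."""
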
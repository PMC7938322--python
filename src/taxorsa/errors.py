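"""Exception hierarchy.

Errors are grouped by the pipeline stage that raises them so the CLI can
map them onto exit codes (config errors vs. data errors).
"""


class TaxoRSAError(Exception):
    """Base class for all package errors."""


class ConfigError(TaxoRSAError):
    """Invalid or inconsistent run configuration (bad paths, missing keys)."""


class DataError(TaxoRSAError):
    """Base class for errors raised by data handling or computation."""


class TaxonomyFormatError(DataError):
    """Malformed taxonomy document (duplicate names, unlabeled internals)."""


class TaxonomyStructureError(DataError):
    """Structurally invalid hierarchy (cycles, multiple roots, unreachable)."""


class NodeLookupError(DataError, KeyError):
    """A concept name is not a node of the taxonomy."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return Exception.__str__(self)


class SchemeError(DataError):
    """Invalid superordinate scheme (ancestral names, empty scheme)."""


class SizeError(DataError):
    """An input is too small for the requested statistic."""


class ParameterError(DataError):
    """A numeric parameter is outside its admissible range."""


class AlignmentError(DataError):
    """Two objects that must share a category index do not."""


class DegenerateInputError(DataError):
    """A computation received input with no usable variation."""


class DegeneratePatternError(DegenerateInputError):
    """A category response pattern has zero variance across units."""


class ParseError(DataError):
    """A delimited input file violates its expected layout."""
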
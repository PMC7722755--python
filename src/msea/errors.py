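"""Exception hierarchy for the msea package.

All domain errors derive from :class:`MseaError` so callers (and the CLI)
can catch package errors with a single except clause.
"""


class MseaError(Exception):
    """Base class for all msea-specific errors."""


class InvalidNameError(MseaError, ValueError):
    """A taxon name is empty after normalization."""


class MalformedLineageError(MseaError, ValueError):
    """A lineage string violates rank ordering."""


class InvalidRankError(MseaError, ValueError):
    """A taxonomic rank is not usable for the requested operation."""


class EmptyLibraryError(MseaError, ValueError):
    """No usable records remained to build a set library."""


class FormatError(MseaError, ValueError):
    """A file does not conform to its declared format.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class EmptyCorpusError(MseaError, ValueError):
    """The mention corpus has no document carrying both entity kinds."""


class NoValidThresholdError(MseaError, ValueError):
    """Every candidate threshold fraction was degenerate."""


class UniverseTooSmallError(MseaError, ValueError):
    """The requested universe cannot contain all named members."""


class EmptyInputError(MseaError, ValueError):
    """The input microbe set is empty (possibly after universe filtering)."""


class EmptyResultError(MseaError, ValueError):
    """An operation that needs enrichment results received none."""


class InsufficientDataError(MseaError, ValueError):
    """Too few observations for the requested embedding."""


class SimulationSpecError(MseaError, ValueError):
    """A synthetic-data specification is internally inconsistent."""


class DomainError(MseaError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""


class UnknownEntityError(MseaError, KeyError):
    """An entity name is absent from the container being queried."""
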
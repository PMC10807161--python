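"""Exception hierarchy shared across the package."""

from __future__ import annotations

__all__ = [
    "VteriskError",
    "IdentificationError",
    "InsufficientDataError",
    "DegenerateRatingsError",
    "ConfigurationError",
    "MatrixError",
    "ConvergenceError",
    "InstrumentError",
    "ParseError",
]


class VteriskError(Exception):
    """Base class for all package errors."""


class IdentificationError(VteriskError, KeyError):
    """An expert, item, indicator or dimension label is unknown."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return Exception.__str__(self)


class InsufficientDataError(VteriskError, ValueError):
    """Too few responses to compute the requested statistic."""


class DegenerateRatingsError(VteriskError, ValueError):
    """All ratings identical: concordance is undefined (0/0), not zero."""


class ConfigurationError(VteriskError, ValueError):
    """A lookup table (Cs map, Ca table, RI table) is missing an entry."""


class MatrixError(VteriskError, ValueError):
    """A judgment matrix violates its structural invariants."""


class ConvergenceError(VteriskError, RuntimeError):
    """Power iteration failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class InstrumentError(VteriskError, ValueError):
    """An instrument file violates its schema or its structural counts."""


class ParseError(VteriskError, ValueError):
    """A CSV/YAML input could not be parsed; carries file and line context."""
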
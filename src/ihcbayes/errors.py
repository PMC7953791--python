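"""Exception taxonomy shared across the package.

All exceptions derive from :class:`IhcBayesError` so callers can catch
package failures with a single handler while still discriminating the
fine-grained classes the CLI maps to exit codes.
"""

from __future__ import annotations


class IhcBayesError(Exception):
    """Base class for every error raised by this package."""


class VocabularyError(IhcBayesError, ValueError):
    """A positivity term is not in the encoding vocabulary."""


class RangeError(IhcBayesError, ValueError):
    """A probability or percentage lies outside its admissible interval."""


class ArgumentError(IhcBayesError, ValueError):
    """A structurally invalid argument (empty list, bad ratio, ...)."""


class UnknownAntibodyError(IhcBayesError, KeyError):
    """An antibody name cannot be resolved against the registry."""

    def __init__(self, name: str, candidates: list[str] | None = None):
        self.name = name
        self.candidates = candidates or []
        msg = f"unknown antibody {name!r}"
        if self.candidates:
            msg += f"; nearest candidates: {', '.join(self.candidates)}"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class UnknownDiseaseError(IhcBayesError, KeyError):
    """A disease identifier is absent from the knowledge base."""

    def __str__(self) -> str:
        return self.args[0]


class RegistryIntegrityError(IhcBayesError):
    """The antibody registry violates its uniqueness invariants."""


class LoadError(IhcBayesError):
    """A file cannot be parsed; carries row/column coordinates when known."""

    def __init__(self, message: str, *, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)


class NoOverlapError(IhcBayesError):
    """No panel marker contributed a likelihood factor for a disease."""


class EmptyDifferentialError(IhcBayesError):
    """No disease in the knowledge base could be scored for a panel."""


class DegenerateTableError(IhcBayesError, ValueError):
    """A contingency table has a zero margin."""
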
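"""Exception hierarchy for pedigraph."""

from __future__ import annotations


class PedigraphError(Exception):
    """Base class for all pedigraph errors."""


class TrioFormatError(PedigraphError):
    """A trio file could not be parsed (missing column, bad dialect)."""


class TrioValidationError(PedigraphError):
    """A trio table violates a structural invariant.

    ``details`` holds one human-readable string per offending record.
    """

    def __init__(self, message: str, details: list[str] | None = None):
        self.details = details or []
        if self.details:
            message = f"{message}: {'; '.join(self.details)}"
        super().__init__(message)


class CyclicParentageError(TrioValidationError):
    """The parental edges contain a directed cycle (someone is their own
    ancestor). ``cycle`` lists the node IDs of one offending cycle."""

    def __init__(self, cycle: list[str]):
        self.cycle = list(cycle)
        super().__init__(f"cyclic parentage: {' -> '.join(self.cycle + self.cycle[:1])}")


class UnknownIDError(PedigraphError, KeyError):
    """An individual ID was requested that is not present in the graph."""

    def __init__(self, ids):
        self.ids = sorted(ids) if not isinstance(ids, str) else [ids]
        super().__init__(f"unknown individual ID(s): {', '.join(self.ids)}")

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0]


class AmbiguousParentError(PedigraphError):
    """Trio reconstruction could not assign father/mother roles."""
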
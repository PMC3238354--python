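"""Exception hierarchy shared by all enrichkit modules."""


class EnrichKitError(Exception):
    """Base class for all errors raised by enrichkit."""


class ParseError(EnrichKitError):
    """A malformed line or document in one of the flat-file dialects.

    Carries the 1-based line number (or document name) where known.
    """

    def __init__(self, message: str, line: int | None = None, source: str | None = None):
        loc = []
        if source is not None:
            loc.append(source)
        if line is not None:
            loc.append(f"line {line}")
        prefix = f"[{', '.join(loc)}] " if loc else ""
        super().__init__(prefix + message)
        self.line = line
        self.source = source


class InputError(EnrichKitError):
    """Invalid user input: empty lists, empty collections, values out of range."""


class DegenerateTableError(EnrichKitError):
    """A 2x2 contingency table with a zero margin; the exact test is undefined."""


class DataError(EnrichKitError):
    """Semantically invalid data, e.g. a negative expression intensity."""


class CycleError(EnrichKitError):
    """The ontology parent-edge relation contains a cycle."""


class NoInteractionDataError(EnrichKitError):
    """The expansion seed gene is incident to no interaction pair."""


class FixtureSpecError(EnrichKitError):
    """An infeasible synthetic-fixture specification."""
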
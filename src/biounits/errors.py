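"""Exception hierarchy for structure parsing, library handling and search."""


class BiounitsError(Exception):
    """Base class for all package errors."""


class ParseError(BiounitsError):
    """Input text could not be parsed into a molecule."""


class UnsupportedStructureError(ParseError):
    """Structure contains features we refuse to process (R-groups, dummies)."""


class KeggLookupError(BiounitsError):
    """Compound identifier not present in the local lookup table."""


class LibraryFormatError(BiounitsError):
    """Malformed unit-library file."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigurationError(BiounitsError):
    """Invalid configuration (empty seed set, empty query library, ...)."""


class ContractViolation(BiounitsError):
    """An internal precondition was violated (embedding outside fragment, ...)."""


class SearchSpaceExceeded(BiounitsError):
    """Fragment-network construction hit a hard cap (node count or depth)."""
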
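"""Exception hierarchy shared by all ontosim modules."""


class OntosimError(Exception):
    """Base class for all errors raised by ontosim."""


class ParseError(OntosimError):
    """Malformed input line or document; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class FormatError(OntosimError):
    """An artifact or document is not in the expected format."""


class VersionError(FormatError):
    """An artifact declares a format version this build does not support."""


class ConfigError(OntosimError):
    """Invalid or incomplete run configuration."""


class ValidationError(OntosimError):
    """Input data violates a documented contract (e.g. negative counts)."""


class MissingConceptError(OntosimError):
    """A requested concept id is absent from the taxonomy or graph."""

    def __init__(self, concept: str):
        self.concept = concept
        super().__init__(f"unknown concept: {concept!r}")
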
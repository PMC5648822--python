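"""Exception hierarchy shared across the pipeline."""


class SyntelogPhyloError(Exception):
    """Base class for all package errors."""


class ParseError(SyntelogPhyloError):
    """A file could not be parsed; carries path and (1-based) line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        elif line is not None:
            loc += f" [line {line}]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class ValidationError(SyntelogPhyloError):
    """Input violated a structural invariant (duplicate ids, unknown genes...)."""


class ConfigurationError(SyntelogPhyloError):
    """Mutually exclusive or out-of-range configuration values."""


class UndefinedComparisonError(SyntelogPhyloError):
    """Two trees share too few leaves for a meaningful distance."""
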
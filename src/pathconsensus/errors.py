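"""Exception hierarchy shared across the package."""


class PathConsensusError(Exception):
    """Base class for all package errors."""


class ParseError(PathConsensusError):
    """A file is structurally invalid. Carries the offending location."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)


class ValidationError(PathConsensusError):
    """Input violates a semantic contract (wrong classes, bad counts, ...)."""


class DomainError(ValidationError):
    """Numeric arguments outside the mathematically valid domain."""
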
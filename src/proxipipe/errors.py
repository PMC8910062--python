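"""Exception hierarchy shared across the pipeline."""


class ProxipipeError(Exception):
    """Base class for all pipeline errors."""


class ParseError(ProxipipeError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)


class ValidationError(ProxipipeError):
    """Input data violate a structural invariant."""
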
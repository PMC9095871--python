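"""Exception types shared across the toolkit."""


class GrrError(Exception):
    """Base class for all toolkit errors."""


class ParseError(GrrError, ValueError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


class ValidationError(GrrError, ValueError):
    """An object violates a domain invariant (coordinates, genome membership...)."""


class GenomeMismatchError(ValidationError):
    """Two objects that must share a coordinate universe do not."""
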
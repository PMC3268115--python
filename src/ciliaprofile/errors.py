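"""Exception hierarchy shared across the pipeline stages."""


class CiliaProfileError(Exception):
    """Base class for all package-specific errors."""


class HitParseError(CiliaProfileError, ValueError):
    """A similarity-search line could not be parsed; carries the line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


class ConfigError(CiliaProfileError, ValueError):
    """Inconsistent or incomplete configuration."""


class InputError(CiliaProfileError, ValueError):
    """Input data violates a precondition (unknown species, shape mismatch...)."""
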
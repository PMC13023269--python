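"""Exception types shared across the toolkit."""


class DimensionError(ValueError):
    """Array shapes are inconsistent with an operation's contract."""


class ConfigurationError(ValueError):
    """A configuration value is unknown or internally inconsistent."""


class SchemaError(ValueError):
    """An annotation violates the six-class box schema."""


class ParseError(ValueError):
    """A label file line could not be parsed."""

    def __init__(self, message: str, line_no: int | None = None):
        self.line_no = line_no
        super().__init__(message if line_no is None
                         else f"line {line_no}: {message}")


class GenerationError(RuntimeError):
    """Scene synthesis could not satisfy the requested constraints."""
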
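class PorefluxError(Exception):
    """Base class for user-facing errors."""


class ValidationError(PorefluxError):
    """Invalid input data or parameters."""


class ParseError(PorefluxError):
    """Malformed input file."""


class FitError(PorefluxError):
    """A model fit failed to converge or is degenerate."""
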
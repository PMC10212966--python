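"""Exception hierarchy shared across the package."""


class ThermoshiftError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(ThermoshiftError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(ThermoshiftError, ValueError):
    """Input is structurally valid but carries no usable signal
    (e.g. all-zero quantities, zero variance everywhere)."""


class ValidationError(ThermoshiftError, ValueError):
    """A file or configuration failed schema validation."""
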
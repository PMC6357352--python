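"""Exception hierarchy shared across the package."""


class DeepDRError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(DeepDRError, ValueError):
    """Raised when an input table or configuration violates a documented invariant."""


class NumericalError(DeepDRError, RuntimeError):
    """Raised when a computation produces non-finite values (e.g. NaN loss)."""
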
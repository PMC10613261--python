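"""Exception types shared across the package."""


class XpfineError(Exception):
    """Base class for all package-specific errors."""


class InputError(XpfineError, ValueError):
    """Malformed or unusable input data (bad matrix, empty intersection, ...)."""


class ConfigurationError(XpfineError, ValueError):
    """Invalid option/column-mapping/parameter configuration."""


class NumericalError(XpfineError, RuntimeError):
    """A linear-algebra step failed beyond recoverable ridge retries."""
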
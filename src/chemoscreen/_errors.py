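"""Exception types shared across the package."""


class ChemoscreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ChemoscreenError):
    """A parameter, flag, or column selection is invalid."""


class ValidationError(ChemoscreenError):
    """Input data violates a structural invariant."""
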
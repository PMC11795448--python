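"""Exception types shared across the package."""


class SemharmError(Exception):
    """Base class for package-specific errors."""


class ConfigurationError(SemharmError, ValueError):
    """A configuration (column map, parameter set, run config) is invalid."""


class EmptyInputError(SemharmError, ValueError):
    """An operation received an input with no usable rows/items/pairs."""


class CapabilityError(SemharmError, RuntimeError):
    """An optional capability (model backend, projection method) is unavailable."""
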
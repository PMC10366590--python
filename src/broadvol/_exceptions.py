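"""Exception hierarchy shared across the package."""


class BroadvolError(Exception):
    """Base class for all package-specific errors."""


class DimensionalityError(BroadvolError, ValueError):
    """An image does not have exactly three spatial axes."""


class ConfigurationError(BroadvolError, ValueError):
    """An invalid or unknown configuration value."""


class StructuralError(BroadvolError, ValueError):
    """Array shapes are incompatible with the model structure."""


class NotFittedError(BroadvolError, RuntimeError):
    """A model was used for prediction before being fitted."""


class PhantomSpecError(BroadvolError, ValueError):
    """A phantom specification is geometrically impossible."""
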
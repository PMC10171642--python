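"""Exception hierarchy shared across the package."""


class HypnofuseError(Exception):
    """Base class for all package-specific errors."""


class AnnotationParseError(HypnofuseError, ValueError):
    """A multi-scorer annotation file could not be parsed."""


class ConfigurationError(HypnofuseError, ValueError):
    """A parameter or configuration value is outside its valid range."""


class DimensionError(HypnofuseError, ValueError):
    """Array shapes of two related objects do not agree."""


class UndefinedValueError(HypnofuseError, ValueError):
    """A quantity is mathematically undefined for the given input."""


class SimulationError(HypnofuseError, RuntimeError):
    """The synthetic generator produced an invalid configuration or sample."""


class TrainingError(HypnofuseError, RuntimeError):
    """Model training failed (e.g. non-finite loss)."""
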
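"""Exception hierarchy."""


class KinreadError(Exception):
    """Base class for package errors."""


class ConfigurationError(KinreadError, ValueError):
    """Invalid configuration value."""


class GenerationError(KinreadError, RuntimeError):
    """Synthetic-data generation produced an invalid quantity."""


class SchemaError(KinreadError, ValueError):
    """Input table/object does not match the expected schema."""


class FittingError(KinreadError, RuntimeError):
    """Model fitting failed or was called on degenerate input."""


class MovementDetectionError(KinreadError, ValueError):
    """Movement onset/offset could not be located."""
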
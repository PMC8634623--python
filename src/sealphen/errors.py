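"""Exception types shared across the package."""


class SealphenError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SealphenError, ValueError):
    """Invalid simulation / pipeline configuration."""


class InsufficientDataError(SealphenError, ValueError):
    """Not enough observations to perform the requested operation."""


class SchemaError(SealphenError, ValueError):
    """A tabular dataset violates its declared schema."""


class ModelError(SealphenError, ValueError):
    """A model is mis-specified or undefined for the given input."""
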
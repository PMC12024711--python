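"""Exception types shared across the package."""


class SplenoptError(Exception):
    """Base class for package errors."""


class SchemaError(SplenoptError):
    """A required column is missing, misnamed, or of the wrong type."""


class ConfigurationError(SplenoptError):
    """Invalid specification, grid, or run configuration."""


class EstimationError(SplenoptError):
    """A nuisance model cannot be fit (e.g. an arm too sparse for cross-fitting)."""


class AlignmentError(SplenoptError):
    """Row indices of two objects that must be aligned do not match."""


class UndefinedValueError(SplenoptError):
    """A requested quantity is undefined for the given input (e.g. a rate on zero rows)."""
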
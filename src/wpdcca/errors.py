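"""Exception hierarchy used across the package."""


class WpdccaError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(WpdccaError):
    """Invalid configuration value or parameter combination."""


class DataError(WpdccaError):
    """Malformed or inconsistent input data."""


class SchemaError(DataError):
    """A required column or field is missing."""


class FormatError(DataError):
    """Structurally invalid data (unequal channel lengths, bad time axis)."""


class ParseError(DataError):
    """Unparseable cell content in an input file."""


class MetricError(WpdccaError):
    """A performance metric is undefined for the given inputs."""


class NumericalError(WpdccaError):
    """A numerical procedure failed (singular covariance, degenerate fit)."""
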
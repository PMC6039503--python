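"""Exception hierarchy.

``ConfigError`` covers bad parameters and configuration (CLI exit code 2);
``DataError`` covers malformed or inconsistent data (CLI exit code 3).
"""


class SweepScanError(Exception):
    """Base class for all package errors."""


class ConfigError(SweepScanError):
    """Invalid parameter, option or configuration value."""


class SchemaError(ConfigError):
    """A tabular input is missing required columns."""


class DataError(SweepScanError):
    """Input data violates an invariant the pipeline relies on."""


class ParseError(DataError):
    """A file could not be parsed; the message names the offending line."""


class PlacementError(DataError):
    """Simulated features could not be placed in the given genome."""
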
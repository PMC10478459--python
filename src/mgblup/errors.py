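"""Exception hierarchy used across the package.

The command-line interface maps these onto exit codes (2: configuration,
3: data, 4: numerical failure).
"""


class MgblupError(Exception):
    """Base class for package errors."""


class ConfigurationError(MgblupError):
    """Invalid configuration: impossible designs, bad thresholds, bad scenarios."""


class DataFormatError(MgblupError):
    """Malformed or inconsistent input data."""


class NumericalError(MgblupError):
    """Numerical failure (singular systems, undefined denominators)."""
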
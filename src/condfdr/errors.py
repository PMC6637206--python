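"""Exception hierarchy shared across the package.

The command-line layer maps these onto process exit codes: configuration
and input problems exit with 1, computation failures with 2.
"""


class CondFdrError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CondFdrError):
    """A configuration value (column mapping, grid, threshold) is invalid."""


class InputError(CondFdrError):
    """Input data are unusable (no valid rows, empty intersection, ...)."""


class ComputationError(CondFdrError):
    """A computation cannot proceed on the given data."""
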
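"""Exception hierarchy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class VaxbiomeError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(VaxbiomeError):
    """Invalid configuration (bad parameter values, missing files)."""


class DataError(VaxbiomeError):
    """Malformed or degenerate input data."""


class ParseError(DataError):
    """A table file could not be parsed; message carries the line number."""
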
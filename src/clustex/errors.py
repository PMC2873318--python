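"""Exception hierarchy shared by all stages.

ConfigurationError maps to CLI exit code 2, FormatError to exit code 3.
"""


class ClustExError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(ClustExError, ValueError):
    """A parameter or configuration value is invalid or missing."""


class FormatError(ClustExError, ValueError):
    """An input file violates its expected format."""
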
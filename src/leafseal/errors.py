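"""Exception hierarchy shared across the package.

The CLI maps :class:`ConfigError` to exit code 2 and :class:`DataError`
to exit code 3; everything else is an ordinary traceback.
"""


class LeafSealError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(LeafSealError):
    """Invalid configuration or parameter values."""


class DataError(LeafSealError):
    """Invalid, inconsistent or degenerate input data."""
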
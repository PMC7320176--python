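"""Exception hierarchy.

``ConfigError`` covers malformed configuration (bad keys, infeasible
parameters); ``DataError`` covers invalid or missing input data. The CLI maps
them to exit codes 2 and 1 respectively.
"""


class SBScreenError(Exception):
    """Base class for all package errors."""


class ConfigError(SBScreenError):
    """Invalid or infeasible configuration."""


class DataError(SBScreenError):
    """Invalid, inconsistent, or missing input data."""
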
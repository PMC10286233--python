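"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3.
"""


class DivaseError(Exception):
    """Base class for all package errors."""


class ConfigError(DivaseError):
    """Invalid configuration (bad thresholds, degenerate simulation settings)."""


class DataError(DivaseError):
    """Malformed or inconsistent input data (row-addressed where possible)."""
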
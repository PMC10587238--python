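"""Exception hierarchy shared across the pipeline.

Exit-code mapping used by the CLI: ConfigurationError -> 2, everything
else derived from AllomethermError -> 1.
"""


class AllomethermError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AllomethermError):
    """Invalid configuration (bad ranges, non-positive volumes, ...)."""


class DataError(AllomethermError):
    """Malformed or physically impossible input data."""


class DomainError(AllomethermError):
    """Arguments outside the mathematical domain of an operation."""


class InsufficientDataError(DataError):
    """Too few observations to apply an estimator."""
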
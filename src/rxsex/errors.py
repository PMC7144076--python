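"""Exception hierarchy shared across the package."""


class RxSexError(Exception):
    """Base class for all package-specific errors."""


class ParseError(RxSexError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(RxSexError):
    """Input values violate an invariant (negative counts, empty table, ...)."""


class ConfigurationError(RxSexError):
    """A karyotype or classifier configuration is inconsistent."""


class InsufficientDataError(RxSexError):
    """Not enough usable chromosomes or reads to compute the statistic."""
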
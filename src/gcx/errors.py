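"""Exception taxonomy shared across the pipeline."""


class GcxError(Exception):
    """Base class for all package errors."""


class ParseError(GcxError):
    """A malformed input row; message names the offending line."""


class ValidationError(GcxError):
    """An input value outside its allowed domain."""


class ContractViolation(GcxError):
    """A caller broke an operation's precondition."""


class ConfigurationError(GcxError):
    """Missing or inconsistent configuration (catalog, lengths, params)."""


class UndefinedResultError(GcxError):
    """The requested statistic is undefined for this input (e.g. zero denominator)."""


class CalibrationError(GcxError):
    """A simulator calibration target cannot be met."""
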
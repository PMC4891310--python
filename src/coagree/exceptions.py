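"""Exception hierarchy for coagree."""


class CoagreeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CoagreeError):
    """A dataset file does not match the documented column schema."""


class ValidationError(CoagreeError):
    """One or more rows violate a field-level invariant."""


class ConfigurationError(CoagreeError):
    """A simulation or analysis configuration field is invalid."""


class InsufficientDataError(CoagreeError):
    """Too few usable pairs to compute the requested statistic."""


class DegenerateTestError(CoagreeError):
    """A statistical test is undefined on this input (e.g. Wilcoxon with all-zero differences)."""


class EmptyAfterQcError(CoagreeError):
    """Every paired sample was flagged by quality control; nothing left to analyse."""
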
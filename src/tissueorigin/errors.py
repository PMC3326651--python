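"""Exception types raised across the package."""


class TissueOriginError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TissueOriginError, ValueError):
    """An argument violates an operation's precondition."""


class SchemaError(TissueOriginError, ValueError):
    """A table or profile is missing a required field or identifier."""


class DegenerateLabelsError(TissueOriginError, ValueError):
    """Both classes are required but only one (or none) is present."""


class UndefinedStatisticError(TissueOriginError, ValueError):
    """The requested statistic has no defined value (e.g. n = 0)."""


class DataExhaustedError(TissueOriginError, ValueError):
    """An input stream is shorter than the schedule it must cover."""
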
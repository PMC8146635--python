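"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`ZfSleepError` so orchestration code
can abort with the stage name and the offending subject attached.
"""


class ZfSleepError(Exception):
    """Base class for all package errors."""


class FormatError(ZfSleepError):
    """A tracking table or config file does not match the declared dialect."""


class ValidationError(ZfSleepError):
    """Input data violates a structural invariant (e.g. non-monotonic time)."""


class RangeError(ZfSleepError):
    """A requested window or phase lies outside the recorded span."""


class GeometryError(ZfSleepError):
    """Arena zones fail to tile the arena footprint."""


class ConfigError(ZfSleepError):
    """A run configuration is incomplete or internally inconsistent."""


class ComputationError(ZfSleepError):
    """A metric is requested on degenerate input (e.g. zero analyzed seconds)."""


class StatisticsError(ZfSleepError):
    """A statistical routine received degenerate groups."""


class NormalizationError(ZfSleepError):
    """Control-normalisation attempted against a zero control mean."""
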
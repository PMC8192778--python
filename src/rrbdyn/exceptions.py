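"""Exception hierarchy.

All package errors derive from :class:`RRBDynError` so callers can catch one
base class; subtypes distinguish bad user input from degenerate numerics.
"""


class RRBDynError(Exception):
    """Base class for all errors raised by rrbdyn."""


class InputError(RRBDynError):
    """A required input (file, column, network) is missing or malformed."""


class ValidationError(RRBDynError):
    """Input was read but violates an invariant (NaN cell, duplicate id...)."""


class ParameterError(RRBDynError):
    """An operation was called with invalid parameters."""


class DegenerateWindowError(RRBDynError):
    """A sliding window has zero weighted variance in some channel."""

    def __init__(self, channel: str, onset: int | None = None):
        self.channel = channel
        self.onset = onset
        where = f" at window onset {onset}" if onset is not None else ""
        super().__init__(f"zero weighted variance in channel {channel!r}{where}")


class GenerationError(RRBDynError):
    """The synthetic generator could not satisfy its constraints."""


class ClusteringError(RRBDynError):
    """State clustering failed (e.g. unrecoverable empty clusters)."""


class InferenceError(RRBDynError):
    """A statistical test was requested on inadmissible data."""


class ConfigurationError(RRBDynError):
    """Pipeline / cross-validation configuration is infeasible."""


class SpecificationError(RRBDynError):
    """A circuit specification names a role absent from the data."""


class PipelineStageError(RRBDynError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.__cause__ = cause
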
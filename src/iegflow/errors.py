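"""Package-specific exception types.

Every rejected precondition in the pipeline raises one of these named
errors so callers (and the CLI) can distinguish user error from bugs.
"""


class IEGFlowError(Exception):
    """Base class for all iegflow errors."""


class ConfigError(IEGFlowError, ValueError):
    """Invalid generator or run configuration."""


class ScheduleError(IEGFlowError, ValueError):
    """Unknown protocol or inconsistent session schedule."""


class MaskError(IEGFlowError, ValueError):
    """Empty or out-of-bounds ROI mask."""


class NormalizationError(IEGFlowError, ValueError):
    """Degenerate input to a normalization (e.g. constant IEG matrix)."""


class DimensionError(IEGFlowError, ValueError):
    """Mismatched shapes / time bases between inputs."""


class AnalysisError(IEGFlowError, ValueError):
    """Analysis precondition violated (missing data, too few samples...)."""


class MissingInputError(IEGFlowError, FileNotFoundError):
    """A pipeline stage is missing an upstream output; message names the path."""
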
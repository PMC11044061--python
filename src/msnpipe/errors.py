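"""Exception hierarchy shared across the pipeline stages."""


class MsnpipeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MsnpipeError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(MsnpipeError):
    """An input file or table violates its schema invariants."""


class DegenerateInputError(MsnpipeError):
    """Numerically degenerate input (e.g. zero-variance feature column)."""


class EmptyNetworkError(MsnpipeError):
    """A density threshold retained no edges."""


class UndefinedMetricError(MsnpipeError):
    """A graph metric is undefined for this input (e.g. single node)."""


class DisconnectedNetworkError(MsnpipeError):
    """The operation requires a connected network."""


class EstimabilityError(MsnpipeError):
    """The statistical design is rank deficient (e.g. an empty cell)."""
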
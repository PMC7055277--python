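"""Exception hierarchy shared by all pipeline stages."""


class ODFlowError(Exception):
    """Base class for all odflow errors."""


class InvalidConfigError(ODFlowError, ValueError):
    """A parameter or configuration value violates a precondition."""


class InvalidRecordError(ODFlowError, ValueError):
    """A single input record is malformed (non-finite coordinates etc.)."""


class EmptyResultError(ODFlowError):
    """An operation produced an empty result where content is required."""


class InsufficientDataError(ODFlowError):
    """Not enough data points on one side of a threshold / below a minimum."""


class ContractViolationError(ODFlowError):
    """An internal invariant (row-stochasticity, count conservation) failed."""


class ConvergenceError(ODFlowError):
    """An iterative solver did not reach its tolerance."""


class DegenerateInputError(ODFlowError):
    """The input makes the requested quantity mathematically undefined."""
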
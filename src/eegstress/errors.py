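"""Exception hierarchy shared across the pipeline stages."""


class EegStressError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EegStressError, ValueError):
    """A configuration value is invalid or inconsistent with the data."""


class FormatError(EegStressError, ValueError):
    """An on-disk container is missing arrays or has the wrong layout."""


class DomainError(EegStressError, ValueError):
    """A numeric argument falls outside its mathematical domain."""


class DegenerateInputError(EegStressError, ValueError):
    """Input is degenerate for the requested statistic (e.g. constant data)."""


class ConsistencyError(EegStressError, ValueError):
    """Recordings disagree on sampling rate or channel set."""


class BalanceError(EegStressError, ValueError):
    """Class-balancing preconditions are violated."""


class TrainingError(EegStressError, ValueError):
    """Classifier training preconditions are violated."""


class EvaluationError(EegStressError, ValueError):
    """Evaluation preconditions are violated (e.g. empty test set)."""


class StateError(EegStressError, RuntimeError):
    """An object is used before the required computation happened, or its
    internal structure is inconsistent."""


class ChannelLookupError(EegStressError, KeyError):
    """A requested channel name does not exist in the recording."""
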
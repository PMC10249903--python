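"""Exception hierarchy.

Every error raised deliberately by this package derives from :class:`GaodeError`,
so callers (and the CLI) can distinguish usage problems from bugs.
"""


class GaodeError(Exception):
    """Base class for all errors raised by gaode."""


class ValidationError(GaodeError, ValueError):
    """Invalid parameter values (weights not summing to one, bad priors, ...)."""


class TrainingDataError(GaodeError):
    """Not enough (or unusable) training data for a requested fit."""


class DegenerateDataError(TrainingDataError):
    """Data with zero variance or otherwise unfit for density estimation."""


class MissingDataError(GaodeError):
    """An instance has no present attributes where at least one is required."""


class SchemaError(GaodeError):
    """Table columns do not match what the model or operation expects."""


class FormatError(GaodeError):
    """A model or results file is malformed or has an unknown version."""


class ComparabilityError(GaodeError):
    """Reliability scores from different trained models were mixed.

    SRS values are only meaningful relative to one trained model; comparing
    scores produced under different models is a user error this exception
    surfaces explicitly.
    """
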
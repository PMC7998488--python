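"""Exception hierarchy shared across the package."""


class GGATError(Exception):
    """Base class for all package errors."""


class SchemaError(GGATError):
    """A declared column is missing or the column-role mapping is invalid."""


class ParseError(GGATError):
    """A cell could not be parsed; the message names the offending row/column."""


class ValidationError(GGATError):
    """An object violates a structural invariant (duplicates, shapes, NaNs...)."""


class ConfigError(GGATError):
    """An option value is unknown or out of range."""


class BalanceError(GGATError):
    """Class-balancing was requested on a single-class dataset."""


class EmptyFeatureError(GGATError):
    """A filtering step removed every feature."""


class DegenerateSampleError(GGATError):
    """A sample has no nonzero counts and cannot be library-size normalized."""


class InsufficientReplicatesError(GGATError):
    """A group has too few samples for a two-sample test."""


class TrainingDivergedError(GGATError):
    """The training loss became non-finite."""
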
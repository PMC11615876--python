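"""Exception hierarchy for the glycotwin pipeline.

Every stage raises a subclass of :class:`GlycoTwinError` so callers (and the
CLI) can distinguish pipeline contract violations from programming errors.
"""


class GlycoTwinError(Exception):
    """Base class for all glycotwin errors."""


class InvalidConfigError(GlycoTwinError):
    """A configuration object violates its invariants."""


class InvalidMealError(GlycoTwinError):
    """A meal record has impossible nutrient values."""


class InvalidInputError(GlycoTwinError):
    """Operation inputs violate a precondition (shapes, signs, lengths)."""


class InsufficientDataError(GlycoTwinError):
    """Not enough samples in the requested window to compute a quantity."""


class SchemaError(GlycoTwinError):
    """A table or feature vector does not match the expected schema/registry."""


class InfeasibleFoldsError(GlycoTwinError):
    """The study span cannot support the requested temporal-gap fold layout."""


class DegenerateTargetError(GlycoTwinError):
    """Training targets carry no variance; the model cannot be fit."""


class UnimputableError(GlycoTwinError):
    """A variable cannot be imputed (e.g. it has no observed values)."""


class UndefinedAUCError(GlycoTwinError):
    """AUC is undefined because only one class is present."""


class EmptyCandidatesError(GlycoTwinError):
    """No candidate foods survive the hard exclusion filters."""


class UndefinedProportionsError(GlycoTwinError):
    """Macro proportions are undefined (zero-calorie candidate)."""


class InvalidNRTError(GlycoTwinError):
    """Nutrition Rules Table thresholds are not strictly ordered."""
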
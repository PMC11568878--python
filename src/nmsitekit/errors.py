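"""Exception hierarchy. Every user-facing failure mode has a named class."""


class NmSiteKitError(Exception):
    """Base class for all package errors."""


class WindowOutOfBoundsError(NmSiteKitError):
    """A requested window would run off the end of the sequence."""


class AmbiguousCenterError(NmSiteKitError):
    """The center residue of a window is N (ambiguous)."""


class IllegalResidueError(NmSiteKitError):
    """A residue outside the {A, C, G, U, N} alphabet."""


class InsufficientCandidatesError(NmSiteKitError):
    """Fewer valid negative-window centers than requested.

    Carries ``achieved``: the number of valid candidates that do exist.
    """

    def __init__(self, message: str, achieved: int = 0):
        super().__init__(message)
        self.achieved = achieved


class NegativePoolExhaustedError(NmSiteKitError):
    """Too few negatives to fill the validation/test partitions at the target ratio."""


class UnbalancedStructureError(NmSiteKitError):
    """A dot-bracket string with unmatched parentheses."""


class IllegalStructureCharacterError(NmSiteKitError):
    """A character outside the dot-bracket alphabet."""


class BackendUnavailableError(NmSiteKitError):
    """The requested external structure-folding backend is not installed."""


class InvalidConfigError(NmSiteKitError):
    """A model/training/ensemble configuration violates its constraints."""


class InconsistentCoordinatesError(NmSiteKitError):
    """Z-curve coordinates that do not invert to nonnegative integer counts."""


class NumericalFailureError(NmSiteKitError):
    """A non-finite value appeared during model evaluation or training."""


class SingleClassError(NmSiteKitError):
    """An operation requiring both classes received only one."""
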
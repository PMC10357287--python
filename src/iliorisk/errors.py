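"""Exception types shared across the package."""


class IlioriskError(Exception):
    """Base class for all package errors."""


class InvalidInputError(IlioriskError, ValueError):
    """Raised when an input violates a documented precondition."""


class BoundaryError(IlioriskError):
    """Raised when a probe or span falls outside the vessel extent."""


class InconsistencyError(IlioriskError):
    """Raised when two inputs that must describe the same vessel disagree."""


class CollinearityError(InvalidInputError):
    """Raised when a design matrix is rank deficient.

    ``features`` names the offending column(s).
    """

    def __init__(self, message: str, features=None):
        super().__init__(message)
        self.features = list(features or [])


class SeparationError(IlioriskError):
    """Raised when a logistic fit fails to converge, typically because a
    feature perfectly separates the outcome. ``feature`` names the suspect."""

    def __init__(self, message: str, feature=None):
        super().__init__(message)
        self.feature = feature


class UndefinedStatisticError(IlioriskError):
    """Raised when a statistic is undefined for the given data
    (zero variance, degenerate probabilities, empty class)."""
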
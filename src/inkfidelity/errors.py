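"""Exception hierarchy shared across the package."""


class InkFidelityError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(InkFidelityError, ValueError):
    """A physical or configuration parameter violates its invariants."""


class DomainError(InkFidelityError, ValueError):
    """A query point lies outside the valid domain of a solution."""


class TensionLimitError(InkFidelityError):
    """The tensioned closed form is degenerate; use the classic limit."""


class BracketError(InkFidelityError, ValueError):
    """An inverse problem's target is unattainable within the bracket.

    Carries the achievable interval so callers can widen the bracket.
    """

    def __init__(self, message: str, achievable: tuple[float, float] | None = None):
        super().__init__(message)
        self.achievable = achievable


class NumericalFailureError(InkFidelityError, RuntimeError):
    """A numerical solve produced a singular or non-finite result."""


class SegmentationError(InkFidelityError, RuntimeError):
    """Image segmentation could not find the expected structure."""


class InsufficientDataError(InkFidelityError, ValueError):
    """Too few observations/pixels to compute the requested quantity."""


class FormatError(InkFidelityError, IOError):
    """A file could not be read or does not match the declared layout."""


class FixtureSpecError(InkFidelityError, ValueError):
    """A synthetic-fixture specification is contradictory or infeasible."""
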
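"""Exception hierarchy shared across the package."""


class CoalAfsError(Exception):
    """Base class for all package errors."""


class ValidationError(CoalAfsError, ValueError):
    """A parameter or precondition failed validation."""


class DomainError(CoalAfsError, ValueError):
    """An input lies outside the mathematical domain (e.g. negative time)."""


class NumericDomainError(CoalAfsError, ArithmeticError):
    """A numeric evaluation left the representable/positive domain."""


class UnsupportedFamilyError(CoalAfsError, ValueError):
    """The requested operation has no closed form for this model family."""


class NonCoalescingHistoryError(CoalAfsError, RuntimeError):
    """The scaled time target cannot be reached: the population is too large
    into the past for the lineages to coalesce within the scan guard."""


class DegenerateSpectrumError(CoalAfsError, ValueError):
    """The spectrum has zero total mass and cannot be normalized."""
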
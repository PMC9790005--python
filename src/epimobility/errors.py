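"""Exception types shared across the package."""


class EpimobilityError(Exception):
    """Base class for all package-specific errors."""


class FormatError(EpimobilityError, ValueError):
    """A delimited input file violates its expected layout."""


class ValidationError(EpimobilityError, ValueError):
    """Input data violate a domain invariant (e.g. beta outside [0, 1])."""


class RankError(EpimobilityError, ValueError):
    """A design or reference matrix is rank deficient.

    Carries the names of the aliased (collinear) columns when they can be
    identified.
    """

    def __init__(self, message: str, aliased: list[str] | None = None):
        super().__init__(message)
        self.aliased = aliased or []


class IdentifiabilityError(EpimobilityError, ValueError):
    """A model parameter is not identified by the data supplied."""


class ConvergenceError(EpimobilityError, RuntimeError):
    """An iterative fit failed to converge."""
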
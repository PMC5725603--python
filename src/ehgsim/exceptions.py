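"""Exception hierarchy shared by all ehgsim modules."""


class EHGSimError(Exception):
    """Base class for all ehgsim errors."""


class DomainError(EHGSimError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class SingularityError(EHGSimError, ArithmeticError):
    """A denominator of the source-potential expression vanished.

    The message names the offending term (inner or outer band edge).
    """


class SolverError(EHGSimError, RuntimeError):
    """The finite-difference forward solve failed or did not converge."""


class PlacementError(EHGSimError, ValueError):
    """A source was placed outside the region where it is allowed."""


class FieldQueryError(EHGSimError, ValueError):
    """A potential field was queried outside the solved domain."""


class EstimationError(EHGSimError, RuntimeError):
    """A signal-derived quantity (peak, delay) could not be estimated."""


class ConfigError(EHGSimError, ValueError):
    """A run configuration failed validation; the message names the key."""
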
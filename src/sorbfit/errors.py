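"""Exception hierarchy for sorbfit."""


class SorbfitError(Exception):
    """Base class for all sorbfit errors."""


class DomainError(SorbfitError, ValueError):
    """An input lies outside the mathematical domain of an isotherm or score."""


class RangeOverflowError(DomainError):
    """An intermediate power/exponential would overflow double precision."""


class ValidationError(SorbfitError, ValueError):
    """Structured input (data table, config, bounds) failed validation."""


class ConvergenceError(SorbfitError, RuntimeError):
    """The optimizer failed to produce any converged solution."""
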
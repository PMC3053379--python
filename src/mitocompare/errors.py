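"""Exception hierarchy used across the package."""


class MitocompareError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MitocompareError, ValueError):
    """Input data violates a documented precondition (bad residue, bad range)."""


class ContractViolation(MitocompareError, ValueError):
    """An operation was called outside its documented contract."""


class ConfigurationError(MitocompareError, ValueError):
    """A simulation or analysis configuration is internally inconsistent."""


class UndefinedValueError(MitocompareError, ArithmeticError):
    """A requested statistic is undefined for this input (e.g. GC of all-N)."""


class EstimationError(MitocompareError, RuntimeError):
    """A model fit failed or produced a physically meaningless estimate."""
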
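"""Exception hierarchy; CLI maps these onto exit codes (2 = bad input, 3 = runtime)."""


class IIINetError(Exception):
    """Base class for all package errors."""


class ValidationError(IIINetError):
    """Input data violates a documented invariant."""


class ContractViolation(IIINetError):
    """An operation was called with arguments outside its contract."""


class ConfigError(IIINetError):
    """Configuration values are inconsistent or infeasible."""


class FitError(IIINetError):
    """Model fitting failed to converge."""
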
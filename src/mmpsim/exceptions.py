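"""Exception and warning types shared across mmpsim."""


class MmpsimError(Exception):
    """Base class for all mmpsim errors."""


class ValidationError(MmpsimError, ValueError):
    """An input violates a documented precondition or type invariant."""


class FitError(MmpsimError, RuntimeError):
    """Mixture fitting failed (non-finite likelihood in every start, or a
    decreasing EM log-likelihood, which indicates a numerical defect)."""


class EmptyGateError(ValidationError):
    """A percentile gate selected zero events; the sample is too small for
    the requested fraction."""


class EmptyGateWarning(UserWarning):
    """floor(fraction * N) rounded a requested gate down to zero events."""
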
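"""Exception types shared across the package."""


class CareflowError(Exception):
    """Base class for all package errors."""


class ValidationError(CareflowError):
    """Input data violates a hard invariant (bad date, unknown token, ...)."""

    def __init__(self, message, issues=None):
        super().__init__(message)
        self.issues = list(issues) if issues else []


class ContractError(CareflowError):
    """An operation was called outside its contract (e.g. BOR on an adjuvant line)."""


class FitError(CareflowError):
    """A statistical fit could not be performed (e.g. Cox model with no events)."""
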
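"""Exception types shared across the package."""


class Pif4NetError(Exception):
    """Base class for all package errors."""


class DomainError(Pif4NetError, ValueError):
    """An argument is outside its mathematical domain (e.g. day length > 24 h)."""


class BranchViolationError(Pif4NetError):
    """A closed-form result is inconsistent with the branch it assumes.

    Raised by the below-threshold steady-state oracle when the computed
    PIF4 level sits at or above the autoinhibition threshold, where the
    oracle's algebra does not apply.
    """


class ConfigurationError(Pif4NetError, ValueError):
    """Inconsistent or schema-invalid configuration input."""


class IntegrationError(Pif4NetError, RuntimeError):
    """The ODE solver failed; the message carries the event context."""
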
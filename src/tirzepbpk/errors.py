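"""Exception hierarchy shared across the package."""


class TirzepbpkError(Exception):
    """Base class for package errors."""


class DomainError(TirzepbpkError, ValueError):
    """Input outside the physically or biologically supported domain."""


class ValidationError(TirzepbpkError, ValueError):
    """Structurally invalid object (failed invariant check)."""


class IntegrationError(TirzepbpkError, RuntimeError):
    """ODE solver failure; carries solver diagnostics in the message."""


class CalibrationError(TirzepbpkError, RuntimeError):
    """No feasible parameter draw or calibration could not proceed."""


class NCAError(TirzepbpkError, RuntimeError):
    """Non-compartmental analysis failure (e.g. no identifiable terminal phase)."""
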
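"""Typed exceptions shared across the package.

The scale-space laws have hard domain boundaries (forbidden bands, limiting
scales) that are physical statements, not numerical accidents; they get their
own exception types so callers can distinguish "you asked for an impossible
resolution" from "your input was malformed".
"""


class MacroquantError(Exception):
    """Base class for all package errors."""


class DomainError(MacroquantError, ValueError):
    """Input outside the mathematical domain of an operation."""


class ConfigurationError(MacroquantError, ValueError):
    """Inconsistent or incomplete specification of a run."""


class DegenerateParameterError(DomainError):
    """A parameter value that collapses the law (e.g. G = 0)."""


class ForbiddenScaleError(DomainError):
    """Resolution inside the impassable band of the scale harmonic oscillator."""


class LimitingScaleError(DomainError):
    """Resolution at or beyond the invariant limiting scale lambda_H."""


class RepresentationError(MacroquantError):
    """A field cannot be mapped to the requested representation
    (e.g. rotational flow offered to the wave-function construction)."""


class RegimeError(MacroquantError, ValueError):
    """Parameter combination outside the physical regime of a formula."""


class NumericalBlowupError(MacroquantError, FloatingPointError):
    """NaN/overflow during time stepping; carries the failing step index."""

    def __init__(self, step: int, message: str | None = None):
        self.step = step
        super().__init__(message or f"numerical blow-up at step {step}")


class FitError(MacroquantError, ValueError):
    """Degenerate data offered to a fitting routine."""


class FormatError(MacroquantError, ValueError):
    """Malformed field container; names the offending dataset/attribute."""


class ResolutionWarning(UserWarning):
    """Grid or time step too coarse for the requested accuracy."""
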
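"""Exception hierarchy shared across the package.

``ValidationError`` (and subclasses) map to exit code 2 in the CLI; anything
else is an ordinary crash.
"""


class AmpscreenError(Exception):
    """Base class for all package errors."""


class InputError(AmpscreenError):
    """Malformed user input: bad sequences, bad tables, missing columns."""


class ValidationError(AmpscreenError):
    """Inputs parse but are inconsistent (e.g. layout/measurement mismatch)."""


class ConfigurationError(ValidationError):
    """A required design element is missing (e.g. no media-only wells)."""


class DataError(ValidationError):
    """Measurements are unusable (e.g. all background-corrected values <= 0)."""


class NumericalError(AmpscreenError):
    """A solve or fit failed for numerical reasons."""


class InvalidPoolError(NumericalError):
    """A calibration pool produced non-physical (negative) efficiencies."""


class FitError(NumericalError):
    """A curve fit failed or produced a degenerate model."""
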
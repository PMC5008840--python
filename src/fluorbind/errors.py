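"""Exception and warning types shared across the package."""


class FluorbindError(Exception):
    """Base class for all package errors."""


class ValidationError(FluorbindError, ValueError):
    """Input violates a physical or structural invariant."""


class FormatError(FluorbindError, ValueError):
    """A delimited-text spectrum file does not match the expected layout."""


class ExtrapolationError(FluorbindError, ValueError):
    """Requested wavelength grid falls outside the measured span."""


class InsufficientDataError(FluorbindError, ValueError):
    """Too few usable points for the requested fit."""


class DegenerateSpectrumWarning(UserWarning):
    """Spectrum carries no usable signal (e.g. all-zero intensities)."""


class AntiQuenchingWarning(UserWarning):
    """Fitted quenching slope is negative (intensity rises with quencher)."""


class DroppedPointWarning(UserWarning):
    """A titration point was excluded from a fit (e.g. F >= F0 in the
    double-log transform)."""
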
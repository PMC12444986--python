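"""Exception hierarchy shared across the package."""


class EEMQuenchError(Exception):
    """Base class for all package errors."""


class FormatError(EEMQuenchError, ValueError):
    """A file does not follow the expected on-disk dialect."""


class ValidationError(EEMQuenchError, ValueError):
    """An argument or domain object violates its invariants."""


class GridError(EEMQuenchError, ValueError):
    """A wavelength-grid operation is out of range or mismatched."""


class NumericError(EEMQuenchError, ArithmeticError):
    """A numerical routine diverged or produced non-finite values."""


class UndefinedRatioError(EEMQuenchError, ValueError):
    """A quenching ratio is undefined (non-positive denominator)."""
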
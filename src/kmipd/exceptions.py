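"""Exceptions and warnings used across the package."""


class InvalidInputError(ValueError):
    """Raised when user-supplied coordinates or counts are unusable."""


class InvalidRiskTableError(InvalidInputError):
    """Raised when the number-at-risk table is internally inconsistent."""


class MissingInputError(InvalidInputError):
    """Raised when neither a risk table nor a total sample size is given."""


class DegenerateCurveError(InvalidInputError):
    """Raised when the curve reaches zero survival but later intervals report patients at risk."""


class CalibrationError(ValueError):
    """Raised when the requested censoring fraction cannot be reached, or axis references coincide."""


class ReconstructionWarning(UserWarning):
    """Non-fatal issues during IPD reconstruction (e.g. iteration cap reached)."""


class EmptyIntervalWarning(UserWarning):
    """A reported risk-table interval contains no digitized coordinates."""
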
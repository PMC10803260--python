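"""Exception hierarchy for camfate."""


class CamfateError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CamfateError):
    """An input table violates the expected schema or an invariant."""


class MissingCalibrationError(CamfateError):
    """No male-control rows exist for a requested (compartment, marker)."""


class ZeroDetectionError(CamfateError):
    """The estimated detection rate is zero, so correction is undefined."""


class InsufficientDataError(CamfateError):
    """Too few observations to run the requested procedure."""


class CalibrationFallbackWarning(UserWarning):
    """A marker-specific detection rate was unavailable; the compartment's
    pan-myeloid (Iba1) rate was used instead."""


class ExcludedGroupWarning(UserWarning):
    """A group was excluded from an analysis for being below the minimum size."""
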
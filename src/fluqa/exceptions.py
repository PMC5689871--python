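"""Exception hierarchy for fluqa."""


class FluqaError(Exception):
    """Base class for all fluqa errors."""


class BehindSourceError(FluqaError):
    """A point at or upstream of the X-ray source cannot be projected."""


class ApertureError(FluqaError):
    """Invalid jaw/MLC state (bank crossing, tip out of travel range)."""


class PlanFormatError(FluqaError):
    """Malformed or unsupported DICOM-RT plan content."""


class LogFormatError(FluqaError):
    """Malformed delivery-log file (bad magic, truncation, empty record section)."""


class LogDataError(FluqaError):
    """Physically inconsistent log content (e.g. non-monotone cumulative MU)."""


class GridMismatchError(FluqaError):
    """Two volumes being compared do not share a grid."""


class DegenerateGeometryError(FluqaError):
    """A voxel coincides with the source position."""


class UndefinedCorrelationError(FluqaError):
    """Correlation requested on a zero-variance sample."""
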
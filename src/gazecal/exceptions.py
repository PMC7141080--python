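"""Exception and warning hierarchy for the gaze-calibration pipeline."""


class GazecalError(Exception):
    """Base class for all package errors."""


class FormatError(GazecalError):
    """A file does not have the expected structure (e.g. missing CSV column)."""


class ParseError(GazecalError):
    """A cell or field could not be parsed; carries the offending row number."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message)
        self.row = row


class NoPupilFound(GazecalError):
    """No dark connected component of sufficient area in the eye frame."""


class DegenerateContour(GazecalError):
    """Contour polygon too small or self-intersecting for a distance field."""


class NoMarkerFound(GazecalError):
    """No nested dark/light/dark contour triple in the world frame."""


class AmbiguousMarker(GazecalError):
    """More than one high-confidence marker candidate in a single frame."""


class DegenerateGeometry(GazecalError):
    """Calibration pupil geometry does not span the quadratic basis."""

    def __init__(self, message: str, deficient_basis: str | None = None):
        super().__init__(message)
        self.deficient_basis = deficient_basis


class InsufficientCalibrationPoints(GazecalError):
    """Fewer than the minimum calibration pairs after the split."""


class NoNodes(GazecalError):
    """IDW asked to interpolate from an empty node subset."""


class BorderClippedWarning(UserWarning):
    """Detected pupil component touches the image border; result still returned."""
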
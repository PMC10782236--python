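"""Exception and warning hierarchy for cupversion."""


class CupVersionError(Exception):
    """Base class for all cupversion errors."""


class InsufficientDataError(CupVersionError):
    """Fewer input points than the operation requires (e.g. <5 rim points)."""


class DegenerateFitError(CupVersionError):
    """Point configuration does not determine an ellipse (collinear,
    coincident, or otherwise rank-deficient)."""


class NotAnEllipseError(CupVersionError):
    """Conic coefficients do not describe a real ellipse (discriminant >= 0
    or imaginary axes)."""


class DegenerateLandmarkError(CupVersionError):
    """Landmarks coincide where distinct points are required."""


class UnsolvableFlexionError(CupVersionError):
    """Measured pelvic-axis foreshortening falls outside the range the
    anatomical prior can explain, beyond tolerance.

    Carries ``clamped_flexion_deg``, the flexion obtained by clamping the
    foreshortening ratio to the solvable boundary.
    """

    def __init__(self, message: str, clamped_flexion_deg: float):
        super().__init__(message)
        self.clamped_flexion_deg = clamped_flexion_deg


class InvalidMeasurementError(CupVersionError):
    """A measurement lacks the finite (v1, v2) candidate pair the decision
    rule requires."""


class AnnotationSchemaError(CupVersionError):
    """Annotation file fails schema validation; message names the field."""


class CupVersionWarning(UserWarning):
    """Base class for cupversion warnings."""


class CircularCupWarning(CupVersionWarning):
    """Fitted ellipse is (near-)circular: the cup faces the beam and the
    planar version saturates at 90 deg, which is anatomically implausible."""


class DegenerateProjectionWarning(CupVersionWarning):
    """Cup plane is (near-)parallel to the beam; the projected rim collapses
    toward a line segment."""


class PoseSeparationWarning(CupVersionWarning):
    """The two films' pelvic poses are too similar for a reliable
    anteversion/retroversion call."""
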
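"""Per-film cup measurement: inclination, planar version, pelvic pose, and
the paired standardized version angles.

The measurement chain for one AP pelvis radiograph is:

1. Fit an ellipse to the digitized cup-opening rim points.
2. Reference frame from bony landmarks: the inter-teardrop line is the
   pelvic horizontal; the line from the sacrococcygeal-junction midpoint
   (SCJ) to the upper pole of the pubic symphysis (PS) is the pelvic
   radiographic axis.
3. Pelvic pose from those references: in-plane rotation (roll) from the
   axis direction, sagittal flexion from the foreshortening of the axis
   relative to the inter-teardrop distance, using a bilaterally symmetric
   anatomical prior (:class:`PelvisAnatomyModel`).
4. Standardized versions: the projected ellipse constrains the 3D cup
   normal up to the sign of its out-of-film component. Both candidate
   normals are reconstructed, de-rotated by the estimated pose into the
   standardized pelvic frame, and each candidate's signed version (angle of
   the normal above the standardized coronal plane) is reported. The
   anteversion-candidate (larger) angle is ``liaw_v1_deg``, the
   retroversion candidate (smaller) is ``liaw_v2_deg``. A single film
   cannot tell which candidate is physically real; that is the job of
   :mod:`cupversion.decision`.

Coordinates: film x toward the patient's left, y superior, z anterior
(out of the film, toward the tube); all angles in degrees.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import warnings
from typing import Sequence

import numpy as np

from .errors import (
    CircularCupWarning,
    DegenerateLandmarkError,
    InsufficientDataError,
    UnsolvableFlexionError,
)
from .geometry import EllipseParams, Point2D, conic_to_params, fit_ellipse

logger = logging.getLogger(__name__)

__all__ = [
    "LandmarkSet",
    "PoseEstimate",
    "PelvisAnatomyModel",
    "CupMeasurement",
    "inter_teardrop_direction",
    "pelvic_axis",
    "radiographic_inclination",
    "planar_version",
    "estimate_pose",
    "standardized_versions",
    "measure_film",
]

SIDES = ("left", "right")


def _fold_line_angle(deg: float) -> float:
    """Fold an undirected line angle into (-90, 90]."""
    a = (deg + 90.0) % 180.0 - 90.0
    return 90.0 if a == -90.0 else a


def _rot_x(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _rot_z(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclasses.dataclass(frozen=True)
class LandmarkSet:
    """The named landmarks of one AP pelvis radiograph.

    Coordinates are film units; multiply by ``scale_mm_per_unit`` to get mm.
    Angles are scale-invariant, so an incorrect scale affects only reported
    lengths.
    """

    left_teardrop: Point2D
    right_teardrop: Point2D
    scj: Point2D
    ps: Point2D
    rim_points: np.ndarray
    side: str
    scale_mm_per_unit: float = 1.0

    def __post_init__(self) -> None:
        for name in ("left_teardrop", "right_teardrop", "scj", "ps"):
            object.__setattr__(self, name, Point2D(*getattr(self, name)))
        rim = np.asarray(self.rim_points, dtype=float)
        if rim.ndim != 2 or rim.shape[1] != 2:
            raise ValueError("rim_points must be an (n, 2) array")
        if rim.shape[0] < 5:
            raise InsufficientDataError(
                f"need at least 5 rim points, got {rim.shape[0]}"
            )
        object.__setattr__(self, "rim_points", rim)
        if self.left_teardrop == self.right_teardrop:
            raise DegenerateLandmarkError("teardrop landmarks coincide")
        if self.scj == self.ps:
            raise DegenerateLandmarkError("scj and ps landmarks coincide")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")
        if not self.scale_mm_per_unit > 0.0:
            raise ValueError("scale_mm_per_unit must be positive")

    def in_mm(self) -> "LandmarkSet":
        """Return a copy with all coordinates converted to millimetres."""
        s = self.scale_mm_per_unit
        if s == 1.0:
            return self
        return LandmarkSet(
            left_teardrop=Point2D(self.left_teardrop.x * s, self.left_teardrop.y * s),
            right_teardrop=Point2D(
                self.right_teardrop.x * s, self.right_teardrop.y * s
            ),
            scj=Point2D(self.scj.x * s, self.scj.y * s),
            ps=Point2D(self.ps.x * s, self.ps.y * s),
            rim_points=self.rim_points * s,
            side=self.side,
            scale_mm_per_unit=1.0,
        )


@dataclasses.dataclass(frozen=True)
class PoseEstimate:
    """Pelvic pose inferred from one film.

    rotation_deg
        Signed in-plane pelvic rotation: angle of the pelvic radiographic
        axis from the film inferior direction (counter-clockwise positive).
        Equals the in-plane roll of the pelvis about the beam axis.
    flexion_deg
        Sagittal flexion/tilt about the inter-teardrop axis, estimated from
        foreshortening of the pelvic axis (positive tips the superior pelvis
        anteriorly).
    axis_ratio
        Projected |SCJ->PS| / inter-teardrop distance, the foreshortening
        observable the flexion estimate is based on.
    """

    rotation_deg: float
    flexion_deg: float
    axis_ratio: float

    def __post_init__(self) -> None:
        if not self.axis_ratio > 0.0:
            raise ValueError("axis_ratio must be positive")
        if not -90.0 < self.rotation_deg < 90.0:
            raise ValueError("rotation_deg must lie in (-90, 90)")


@dataclasses.dataclass(frozen=True)
class PelvisAnatomyModel:
    """Bilaterally symmetric pelvic landmark geometry in the pelvic frame.

    Pelvic frame: origin at the inter-teardrop midpoint, x toward the
    patient's left, y superior, z anterior; units mm. Teardrops are mirrored
    across the mid-sagittal plane; SCJ and PS lie on it. The anatomical
    prior needed by the flexion estimate — the neutral inclination of the
    SCJ->PS axis out of the coronal plane and its neutral projected-length
    ratio — is derived from the landmark coordinates, so the model is always
    self-consistent; configure it by moving the landmarks.
    """

    left_teardrop: tuple[float, float, float]
    right_teardrop: tuple[float, float, float]
    scj: tuple[float, float, float]
    ps: tuple[float, float, float]
    cup_center_left: tuple[float, float, float]
    cup_radius_mm: float

    def __post_init__(self) -> None:
        if not self.cup_radius_mm > 0.0:
            raise ValueError("cup_radius_mm must be positive")
        if not self.neutral_axis_ratio > 0.0:
            raise ValueError("pelvic axis must have a nonzero coronal projection")

    @property
    def inter_teardrop_mm(self) -> float:
        lt, rt = np.asarray(self.left_teardrop), np.asarray(self.right_teardrop)
        return float(np.linalg.norm(lt - rt))

    @property
    def neutral_axis_angle_deg(self) -> float:
        """Sagittal angle of the SCJ->PS axis out of the coronal plane at
        neutral pose (positive: PS anterior to SCJ)."""
        v = np.asarray(self.ps) - np.asarray(self.scj)
        return math.degrees(math.atan2(v[2], math.hypot(v[0], v[1])))

    @property
    def neutral_axis_ratio(self) -> float:
        """axis_ratio expected at zero flexion (coronal-plane projection of
        the axis over the inter-teardrop distance)."""
        v = np.asarray(self.ps) - np.asarray(self.scj)
        return float(math.hypot(v[0], v[1]) / self.inter_teardrop_mm)

    def cup_center(self, side: str) -> np.ndarray:
        c = np.asarray(self.cup_center_left, dtype=float)
        if side == "right":
            c = c * np.array([-1.0, 1.0, 1.0])
        elif side != "left":
            raise ValueError(f"side must be one of {SIDES}, got {side!r}")
        return c


@dataclasses.dataclass(frozen=True)
class CupMeasurement:
    """One film's cup measurement.

    ``liaw_v1_deg >= liaw_v2_deg`` always; generically v1 is the positive
    anteversion candidate and v2 the negative retroversion candidate. When
    pelvic tilt exceeds the cup's version, both 3D candidates can
    standardize to the same sign — the pair is still reported in
    (larger, smaller) order and the two-film decision handles it.
    """

    liaw_v1_deg: float
    liaw_v2_deg: float
    inclination_deg: float | None = None
    planar_version_deg: float | None = None
    pose: PoseEstimate | None = None
    ellipse: EllipseParams | None = None
    side: str | None = None

    def __post_init__(self) -> None:
        if not (
            math.isfinite(self.liaw_v1_deg) and math.isfinite(self.liaw_v2_deg)
        ):
            raise ValueError("version candidates must be finite")
        if self.liaw_v1_deg < self.liaw_v2_deg:
            raise ValueError("liaw_v1_deg must be >= liaw_v2_deg")

    @classmethod
    def from_version_pair(cls, v1_deg: float, v2_deg: float) -> "CupMeasurement":
        """Build a bare measurement from a printed (v1, v2) pair, e.g. when
        only the reported angles of a film are available."""
        return cls(liaw_v1_deg=float(v1_deg), liaw_v2_deg=float(v2_deg))


def inter_teardrop_direction(landmarks: LandmarkSet) -> tuple[np.ndarray, float]:
    """Unit vector from the right to the left teardrop and its film angle.

    The angle is the undirected line angle versus the +x film axis, folded
    into (-90, 90]: the in-plane roll of the pelvic horizontal.
    """
    v = np.asarray(landmarks.left_teardrop) - np.asarray(landmarks.right_teardrop)
    norm = np.linalg.norm(v)
    if norm == 0.0:
        raise DegenerateLandmarkError("teardrop landmarks coincide")
    u = v / norm
    return u, _fold_line_angle(math.degrees(math.atan2(v[1], v[0])))


def pelvic_axis(landmarks: LandmarkSet) -> tuple[np.ndarray, float]:
    """Unit vector from SCJ to PS and its film angle (degrees versus +x,
    in (-180, 180])."""
    v = np.asarray(landmarks.ps) - np.asarray(landmarks.scj)
    norm = np.linalg.norm(v)
    if norm == 0.0:
        raise DegenerateLandmarkError("scj and ps landmarks coincide")
    return v / norm, math.degrees(math.atan2(v[1], v[0]))


def radiographic_inclination(ellipse: EllipseParams, itl_angle_deg: float) -> float:
    """Acute angle between the ellipse major axis and the inter-teardrop
    line, folded into [0, 90]."""
    d = abs(ellipse.psi_deg - itl_angle_deg) % 180.0
    return min(d, 180.0 - d)


def planar_version(ellipse: EllipseParams) -> float:
    """Unsigned planar version arcsin(b/a) in degrees, in [0, 90].

    A circular fit (b = a) means the cup faces the beam dead-on; 90 deg is
    returned with :class:`CircularCupWarning` rather than raising, leaving
    the plausibility call to the caller.
    """
    ratio = min(ellipse.axis_ratio, 1.0)
    if ratio >= 1.0 - _planar_circle_tol:
        warnings.warn(
            "fitted ellipse is (near-)circular; planar version saturates",
            CircularCupWarning,
            stacklevel=2,
        )
    return math.degrees(math.asin(ratio))


_planar_circle_tol = 1e-9


def estimate_pose(
    landmarks: LandmarkSet,
    model: PelvisAnatomyModel,
    *,
    solvable_tol: float = 0.05,
) -> PoseEstimate:
    """Estimate in-plane rotation and sagittal flexion from the landmarks.

    Rotation is the signed angle of the projected pelvic axis from the film
    inferior direction. Flexion is solved from the foreshortening of the
    pelvic axis normalized by the inter-teardrop distance (the only
    transverse internal scale unaffected by flexion):

        axis_ratio(f) = neutral_axis_ratio * cos(f - phi0) / cos(phi0)

    where ``phi0`` is the neutral sagittal inclination of the axis. The
    cosine gives two flexion candidates ``phi0 +/- arccos(...)``; the one
    of smaller magnitude is reported (flexion is assumed moderate relative
    to the axis inclination). A ratio beyond the solvable maximum by more
    than ``solvable_tol`` (relative) raises :class:`UnsolvableFlexionError`
    carrying the clamped value; within tolerance it is clamped silently.
    """
    lm = landmarks.in_mm()
    u_axis, _ = pelvic_axis(lm)
    rotation = math.degrees(math.atan2(u_axis[0], -u_axis[1]))

    axis_len = math.dist(lm.scj, lm.ps)
    itl_len = math.dist(lm.left_teardrop, lm.right_teardrop)
    ratio = axis_len / itl_len

    phi0 = model.neutral_axis_angle_deg
    cos_arg = ratio * math.cos(math.radians(phi0)) / model.neutral_axis_ratio
    if cos_arg > 1.0 + solvable_tol:
        raise UnsolvableFlexionError(
            f"axis_ratio {ratio:.4f} exceeds the solvable maximum "
            f"(cos argument {cos_arg:.4f})",
            clamped_flexion_deg=phi0,
        )
    spread = math.degrees(math.acos(min(cos_arg, 1.0)))
    candidates = (phi0 - spread, phi0 + spread)
    flexion = min(candidates, key=abs)
    return PoseEstimate(rotation_deg=rotation, flexion_deg=flexion, axis_ratio=ratio)


def standardized_versions(
    ellipse: EllipseParams,
    pose: PoseEstimate,
    itl_angle_deg: float,
    side: str,
) -> tuple[float, float]:
    """The paired standardized version candidates for one film.

    The projected rim ellipse determines the 3D cup normal up to the sign of
    its out-of-film component: in film coordinates both candidates share the
    in-film component (perpendicular to the major axis, magnitude
    cos(planar version), oriented laterally toward the operated ``side``)
    and differ only in the out-of-film component +/- sin(planar version).
    Each candidate is rotated back into the standardized pelvic frame —
    undo the in-plane roll, then the sagittal flexion about the
    inter-teardrop axis — and its standardized version is the signed angle
    of the normal above the standardized coronal plane (equivalently 90 deg
    minus the angle between the normal and the standardized beam axis).

    Returns ``(liaw_v1_deg, liaw_v2_deg)`` = (larger, smaller) candidate.
    At neutral pose these are exactly ``(+planar_version, -planar_version)``.
    """
    if side not in SIDES:
        raise ValueError(f"side must be one of {SIDES}, got {side!r}")
    vp = math.radians(planar_version(ellipse))
    psi = math.radians(ellipse.psi_deg)
    m = np.array([math.sin(psi), -math.cos(psi)])
    s = 1.0 if side == "left" else -1.0
    if abs(m[0]) < 1e-9:
        if m[1] > 0.0:
            m = -m
    elif m[0] * s < 0.0:
        m = -m

    # undo roll, then flexion about the (de-rolled) inter-teardrop axis
    alpha = itl_angle_deg - pose.rotation_deg
    deroll = _rot_z(-pose.rotation_deg)
    deflex = _rot_z(alpha) @ _rot_x(-pose.flexion_deg) @ _rot_z(-alpha)
    back = deflex @ deroll

    angles = []
    for zsign in (1.0, -1.0):
        n_film = np.array(
            [m[0] * math.cos(vp), m[1] * math.cos(vp), zsign * math.sin(vp)]
        )
        n_std = back @ n_film
        angles.append(math.degrees(math.asin(float(np.clip(n_std[2], -1.0, 1.0)))))
    v1, v2 = max(angles), min(angles)
    return v1, v2


def measure_film(
    landmarks: LandmarkSet, model: PelvisAnatomyModel | None = None
) -> CupMeasurement:
    """Run the full single-film measurement chain.

    Fits the rim ellipse, builds the landmark reference frame, estimates the
    pelvic pose and returns the complete :class:`CupMeasurement`. The
    anatomy ``model`` supplies the flexion prior; when omitted the default
    symmetric pelvis is used.
    """
    if model is None:
        from .simulate import default_pelvis_model

        model = default_pelvis_model()
    lm = landmarks.in_mm()
    conic = fit_ellipse(lm.rim_points)
    ellipse = conic_to_params(conic)
    _, itl_angle = inter_teardrop_direction(lm)
    pose = estimate_pose(lm, model)
    inclination = radiographic_inclination(ellipse, itl_angle)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", CircularCupWarning)
        pv = planar_version(ellipse)
    v1, v2 = standardized_versions(ellipse, pose, itl_angle, lm.side)
    logger.info(
        "film(%s): ellipse center=(%.2f, %.2f) a=%.2f b=%.2f psi=%.2f | "
        "pose rot=%.2f flex=%.2f ratio=%.4f | incl=%.2f vp=%.2f v1=%.2f v2=%.2f",
        lm.side,
        ellipse.center.x,
        ellipse.center.y,
        ellipse.a,
        ellipse.b,
        ellipse.psi_deg,
        pose.rotation_deg,
        pose.flexion_deg,
        pose.axis_ratio,
        inclination,
        pv,
        v1,
        v2,
    )
    return CupMeasurement(
        liaw_v1_deg=v1,
        liaw_v2_deg=v2,
        inclination_deg=inclination,
        planar_version_deg=pv,
        pose=pose,
        ellipse=ellipse,
        side=lm.side,
    )
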
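"""Ellipse geometry: direct least-squares conic fitting and parameterization.

The opening of an acetabular cup is a circle in 3D; under a (near-)parallel
x-ray beam it projects onto the film as an ellipse. Everything downstream —
inclination, version, the paired standardized angles — is read off that
ellipse, so the fit must be deterministic and stable even for the short,
noisy arcs a clinician can actually digitize on a radiograph.

This module fits the general conic

    A x^2 + B x y + C y^2 + D x + E y + F = 0

to rim points by minimizing the algebraic residual subject to the
ellipse-guaranteeing constraint ``4AC - B^2 = 1`` (direct least squares in
the numerically stable block formulation), and converts between the conic
coefficients and the geometric parameters (center, semi-axes, orientation).

Conventions
-----------
* Film coordinates: x toward the patient's left, y superior, millimetres.
* ``psi_deg`` is the orientation of the MAJOR axis, counter-clockwise from
  the +x film axis, folded into [0, 180).
* A circle has no preferred axis; its orientation is reported as 0 by
  convention so that results are deterministic.
* Returned conics are normalized so that A + C = 1 (always possible for a
  real ellipse, whose A and C share a sign).
"""

from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple, Sequence

import numpy as np

from .errors import DegenerateFitError, InsufficientDataError, NotAnEllipseError

__all__ = [
    "Point2D",
    "ConicCoefficients",
    "EllipseParams",
    "fit_ellipse",
    "conic_to_params",
    "params_to_conic",
]

#: relative tolerance below which a >= b is considered a circle
_CIRCLE_RTOL = 1e-12


class Point2D(NamedTuple):
    """A point in film coordinates (mm): x toward the patient's left,
    y superior."""

    x: float
    y: float


def _as_point_array(points: Sequence | np.ndarray, min_points: int = 1) -> np.ndarray:
    """Coerce a sequence of points / (n, 2) array to a float array and
    validate finiteness and count."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) point array, got shape {pts.shape}")
    if pts.shape[0] < min_points:
        raise InsufficientDataError(
            f"need at least {min_points} points, got {pts.shape[0]}"
        )
    if not np.all(np.isfinite(pts)):
        raise ValueError("points contain non-finite coordinates")
    return pts


@dataclasses.dataclass(frozen=True)
class ConicCoefficients:
    """Coefficients of ``A x^2 + B x y + C y^2 + D x + E y + F = 0``.

    Construction only requires the coefficients not to vanish simultaneously;
    whether they describe a real ellipse is checked by
    :func:`conic_to_params` (discriminant ``B^2 - 4AC < 0`` and real axes).
    """

    A: float
    B: float
    C: float
    D: float
    E: float
    F: float

    def __post_init__(self) -> None:
        coeffs = (self.A, self.B, self.C, self.D, self.E, self.F)
        if not all(math.isfinite(c) for c in coeffs):
            raise ValueError("conic coefficients must be finite")
        if max(abs(c) for c in coeffs) == 0.0:
            raise ValueError("conic coefficients are all zero")

    @property
    def discriminant(self) -> float:
        """``B^2 - 4AC``; negative for an ellipse."""
        return self.B * self.B - 4.0 * self.A * self.C

    def normalized(self) -> "ConicCoefficients":
        """Rescale so that A + C = 1 (requires A + C != 0, true for any
        real ellipse)."""
        s = self.A + self.C
        if abs(s) < 1e-300:
            raise NotAnEllipseError("A + C vanishes; conic cannot be an ellipse")
        return ConicCoefficients(
            self.A / s, self.B / s, self.C / s, self.D / s, self.E / s, self.F / s
        )

    def residuals(self, points: Sequence | np.ndarray) -> np.ndarray:
        """Algebraic residual of each point under this conic."""
        pts = _as_point_array(points)
        x, y = pts[:, 0], pts[:, 1]
        return (
            self.A * x * x
            + self.B * x * y
            + self.C * y * y
            + self.D * x
            + self.E * y
            + self.F
        )


@dataclasses.dataclass(frozen=True)
class EllipseParams:
    """Geometric ellipse parameters: center, semi-axes ``a >= b > 0`` (mm)
    and major-axis orientation ``psi_deg`` in [0, 180)."""

    center: Point2D
    a: float
    b: float
    psi_deg: float

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0.0):
            raise ValueError(f"require a >= b > 0, got a={self.a}, b={self.b}")
        if not (0.0 <= self.psi_deg < 180.0):
            raise ValueError(f"psi_deg must lie in [0, 180), got {self.psi_deg}")
        object.__setattr__(self, "center", Point2D(*self.center))

    @property
    def axis_ratio(self) -> float:
        """Minor/major axis ratio b/a in (0, 1]."""
        return self.b / self.a

    def sample(self, n: int) -> np.ndarray:
        """n points evenly spaced in parameter angle along the ellipse."""
        t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
        c, s = math.cos(math.radians(self.psi_deg)), math.sin(math.radians(self.psi_deg))
        x = self.a * np.cos(t)
        y = self.b * np.sin(t)
        return np.column_stack(
            [self.center.x + c * x - s * y, self.center.y + s * x + c * y]
        )


def fit_ellipse(points: Sequence | np.ndarray) -> ConicCoefficients:
    """Fit an ellipse to >= 5 points by direct least squares.

    Minimizes the algebraic residual of the conic over the input points
    subject to the ellipse-specific quadratic constraint ``4AC - B^2 = 1``,
    which guarantees the solution is an ellipse even for noisy short arcs.
    Uses the stable block decomposition of the constrained eigenproblem,
    after centring and scaling the data for conditioning; the returned conic
    is expressed in the original coordinates and normalized to A + C = 1.

    Raises
    ------
    InsufficientDataError
        Fewer than 5 points.
    DegenerateFitError
        Collinear or coincident points, or any configuration that does not
        determine a real ellipse.
    """
    pts = _as_point_array(points, min_points=5)

    centroid = pts.mean(axis=0)
    shifted = pts - centroid
    scale = float(np.sqrt((shifted**2).sum(axis=1)).mean())
    if scale <= 0.0:
        raise DegenerateFitError("all points coincide")
    q = shifted / scale

    x, y = q[:, 0], q[:, 1]
    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t_mat = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rare numeric path
        raise DegenerateFitError("degenerate point configuration") from exc
    m = s1 + s2 @ t_mat
    # premultiply by the inverse of the constraint matrix [[0,0,2],[0,-1,0],[2,0,0]]
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])

    eigval, eigvec = np.linalg.eig(m)
    if np.any(np.abs(eigval.imag) > 1e-8 * (1.0 + np.abs(eigval.real))):
        # complex pair can appear for near-degenerate data
        mask_real = np.abs(eigval.imag) <= 1e-8 * (1.0 + np.abs(eigval.real))
    else:
        mask_real = np.ones(3, dtype=bool)
    vec = eigvec.real
    constraint = 4.0 * vec[0] * vec[2] - vec[1] ** 2
    candidates = np.flatnonzero(mask_real & (constraint > 0.0))
    if candidates.size == 0:
        raise DegenerateFitError(
            "points are collinear or otherwise do not determine an ellipse"
        )
    a1 = vec[:, candidates[0]]
    a2 = t_mat @ a1
    A, B, C = a1
    D, E, F = a2

    # undo the normalization x = (X - cx)/s, y = (Y - cy)/s (times s^2)
    cx, cy = centroid
    Du = D * scale - 2.0 * A * cx - B * cy
    Eu = E * scale - B * cx - 2.0 * C * cy
    Fu = (
        F * scale * scale
        + A * cx * cx
        + B * cx * cy
        + C * cy * cy
        - D * scale * cx
        - E * scale * cy
    )
    conic = ConicCoefficients(A, B, C, Du, Eu, Fu).normalized()
    if conic.discriminant >= 0.0:  # pragma: no cover - constraint should prevent
        raise DegenerateFitError("fit did not yield an ellipse")
    return conic


def conic_to_params(conic: ConicCoefficients) -> EllipseParams:
    """Convert conic coefficients to geometric parameters.

    Raises
    ------
    NotAnEllipseError
        Discriminant ``B^2 - 4AC >= 0``, or the conic is an imaginary or
        point ellipse.
    """
    A, B, C, D, E, F = conic.A, conic.B, conic.C, conic.D, conic.E, conic.F
    disc = B * B - 4.0 * A * C
    if disc >= 0.0:
        raise NotAnEllipseError(f"conic discriminant {disc} >= 0: not an ellipse")

    xc = (2.0 * C * D - B * E) / disc
    yc = (2.0 * A * E - B * D) / disc
    # conic value at the center; ellipse equation becomes
    # [dx dy] Q [dx dy]^T = -fc with Q = [[A, B/2], [B/2, C]]
    fc = A * xc * xc + B * xc * yc + C * yc * yc + D * xc + E * yc + F
    qmat = np.array([[A, B / 2.0], [B / 2.0, C]])
    lam, vecs = np.linalg.eigh(qmat)
    with np.errstate(divide="ignore", invalid="ignore"):
        axes_sq = -fc / lam
    if not np.all(axes_sq > 0.0):
        raise NotAnEllipseError("imaginary or degenerate ellipse (non-positive axes)")
    axes = np.sqrt(axes_sq)
    # smaller eigenvalue of Q <-> longer axis
    order = np.argsort(axes)[::-1]
    a, b = float(axes[order[0]]), float(axes[order[1]])
    if (a - b) <= _CIRCLE_RTOL * a:
        psi = 0.0
        b = a
    else:
        major = vecs[:, order[0]]
        psi = math.degrees(math.atan2(major[1], major[0])) % 180.0
        if psi >= 180.0:  # guard the 180.0 float edge
            psi = 0.0
    return EllipseParams(center=Point2D(float(xc), float(yc)), a=a, b=b, psi_deg=psi)


def params_to_conic(params: EllipseParams) -> ConicCoefficients:
    """Geometric parameters to normalized conic coefficients (A + C = 1)."""
    psi = math.radians(params.psi_deg)
    c, s = math.cos(psi), math.sin(psi)
    ia2, ib2 = 1.0 / params.a**2, 1.0 / params.b**2
    A = c * c * ia2 + s * s * ib2
    B = 2.0 * c * s * (ia2 - ib2)
    C = s * s * ia2 + c * c * ib2
    xc, yc = params.center
    D = -2.0 * A * xc - B * yc
    E = -B * xc - 2.0 * C * yc
    F = A * xc * xc + B * xc * yc + C * yc * yc - 1.0
    return ConicCoefficients(A, B, C, D, E, F).normalized()
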
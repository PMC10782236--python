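"""Synthetic radiograph simulator: forward projection of a parameterized
pelvis and cup-opening circle to landmark sets with known ground truth.

The simulator is the package's validation instrument. It places a circular
cup opening at a known (inclination, signed version) on a bilaterally
symmetric 3D pelvis, applies a per-film pelvic pose (sagittal flexion about
the inter-teardrop axis, in-plane rotation about the beam axis, and
optionally axial obliquity about the vertical axis), projects everything to
film coordinates, and adds seeded isotropic Gaussian landmark noise. Every
measurement and decision operation is testable against the generating
truth without any imaging data.

Geometry
--------
* Pelvic frame: origin at the inter-teardrop midpoint, x toward the
  patient's left, y superior, z anterior. Units mm.
* Cup normal for inclination I, signed version V on side s (+1 left,
  -1 right): ``n = (s sin I cos V, -cos I cos V, sin V)`` — the opening
  faces infero-laterally, tipped anteriorly for V > 0 (anteversion) and
  posteriorly for V < 0 (retroversion).
* Film pose: ``p_film = Rz(rotation) @ Ry(obliquity) @ Rx(flexion) @ p``.
* Projection: orthographic (drop z), matching a parallel beam; an optional
  point-source distance adds perspective magnification for robustness
  experiments only.

Under the orthographic model the projected rim is an ellipse with
``a = cup radius`` and ``b/a = |n_z|``, i.e. planar version =
arcsin(b/a) — the identity the measurement chain inverts.

Noise is applied post-projection in film mm, emulating annotation/click
error, the dominant error source for landmark methods. Draws depend only on
``(seed, film_index)``, not on the noise level, so studies across noise
levels share common random numbers and seeded runs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

from .errors import DegenerateProjectionWarning
from .measure import LandmarkSet, PelvisAnatomyModel, Point2D

__all__ = [
    "SimulationTruth",
    "default_pelvis_model",
    "cup_normal",
    "project_film",
    "simulate_study",
]

# Default anatomy (mm), the single place these constants live. Dimensions
# are adult-scale: inter-teardrop width 130; SCJ posterosuperior and PS
# anteroinferior on the mid-sagittal plane, giving a pelvic radiographic
# axis inclined ~37 deg out of the coronal plane with a neutral
# projected-length ratio of ~0.73 of the inter-teardrop distance; cup
# radius 25 (a 50 mm shell).
_DEFAULT_ANATOMY = {
    "inter_teardrop_mm": 130.0,
    "scj": (0.0, 45.0, -50.0),
    "ps": (0.0, -50.0, 22.0),
    "cup_center_left": (48.0, 12.0, 6.0),
    "cup_radius_mm": 25.0,
}


def default_pelvis_model() -> PelvisAnatomyModel:
    """The default bilaterally symmetric pelvis (constants above)."""
    half = _DEFAULT_ANATOMY["inter_teardrop_mm"] / 2.0
    return PelvisAnatomyModel(
        left_teardrop=(half, 0.0, 0.0),
        right_teardrop=(-half, 0.0, 0.0),
        scj=_DEFAULT_ANATOMY["scj"],
        ps=_DEFAULT_ANATOMY["ps"],
        cup_center_left=_DEFAULT_ANATOMY["cup_center_left"],
        cup_radius_mm=_DEFAULT_ANATOMY["cup_radius_mm"],
    )


@dataclasses.dataclass(frozen=True)
class SimulationTruth:
    """Ground-truth cup orientation and per-film pelvic pose.

    ``true_version_deg`` is signed: negative = retroverted. Noise draws are
    deterministic given ``(seed, film_index)``.
    """

    true_inclination_deg: float = 40.0
    true_version_deg: float = 15.0
    flexion_deg: float = 0.0
    rotation_deg: float = 0.0
    obliquity_deg: float = 0.0
    noise_sd_mm: float = 0.0
    seed: int = 0
    n_rim_points: int = 12
    side: str = "left"
    source_to_film_mm: float | None = None

    def __post_init__(self) -> None:
        if self.n_rim_points < 5:
            raise ValueError("n_rim_points must be >= 5")
        if self.noise_sd_mm < 0.0:
            raise ValueError("noise_sd_mm must be >= 0")
        if self.source_to_film_mm is not None and self.source_to_film_mm <= 0.0:
            raise ValueError("source_to_film_mm must be positive")


def cup_normal(inclination_deg: float, version_deg: float, side: str) -> np.ndarray:
    """Unit cup-opening normal in the pelvic frame."""
    i = math.radians(inclination_deg)
    v = math.radians(version_deg)
    s = 1.0 if side == "left" else -1.0
    return np.array(
        [s * math.sin(i) * math.cos(v), -math.cos(i) * math.cos(v), math.sin(v)]
    )


def _pose_matrix(truth: SimulationTruth) -> np.ndarray:
    f = math.radians(truth.flexion_deg)
    o = math.radians(truth.obliquity_deg)
    r = math.radians(truth.rotation_deg)
    rx = np.array(
        [[1, 0, 0], [0, math.cos(f), -math.sin(f)], [0, math.sin(f), math.cos(f)]]
    )
    ry = np.array(
        [[math.cos(o), 0, math.sin(o)], [0, 1, 0], [-math.sin(o), 0, math.cos(o)]]
    )
    rz = np.array(
        [[math.cos(r), -math.sin(r), 0], [math.sin(r), math.cos(r), 0], [0, 0, 1]]
    )
    return rz @ ry @ rx


def _rim_circle(model: PelvisAnatomyModel, truth: SimulationTruth) -> np.ndarray:
    """3D rim points of the cup-opening circle in the pelvic frame."""
    n = cup_normal(truth.true_inclination_deg, truth.true_version_deg, truth.side)
    seed_vec = np.array([0.0, 1.0, 0.0])
    if abs(n @ seed_vec) > 0.9:
        seed_vec = np.array([0.0, 0.0, 1.0])
    u = np.cross(seed_vec, n)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    t = np.linspace(0.0, 2.0 * np.pi, truth.n_rim_points, endpoint=False)
    center = model.cup_center(truth.side)
    return (
        center
        + model.cup_radius_mm * np.cos(t)[:, None] * u
        + model.cup_radius_mm * np.sin(t)[:, None] * v
    )


def project_film(
    model: PelvisAnatomyModel, truth: SimulationTruth, film_index: int = 0
) -> LandmarkSet:
    """Forward-project one film: pose, projection, seeded noise.

    Warns with :class:`DegenerateProjectionWarning` when the posed cup plane
    is within 0.5 deg of containing the beam axis (the projected rim then
    collapses toward a segment and the ellipse fit is ill-conditioned).
    """
    rot = _pose_matrix(truth)

    points3d = np.vstack(
        [
            np.asarray(model.left_teardrop, float),
            np.asarray(model.right_teardrop, float),
            np.asarray(model.scj, float),
            np.asarray(model.ps, float),
            _rim_circle(model, truth),
        ]
    )
    posed = points3d @ rot.T

    n_posed = rot @ cup_normal(
        truth.true_inclination_deg, truth.true_version_deg, truth.side
    )
    if abs(n_posed[2]) < math.sin(math.radians(0.5)):
        warnings.warn(
            "cup plane is (near-)parallel to the beam; projected rim is "
            "(near-)degenerate",
            DegenerateProjectionWarning,
            stacklevel=2,
        )

    film = posed[:, :2].copy()
    if truth.source_to_film_mm is not None:
        # point source on the beam axis, anterior of the film plane
        mag = truth.source_to_film_mm / (truth.source_to_film_mm - posed[:, 2])
        film *= mag[:, None]

    if truth.noise_sd_mm > 0.0:
        rng = np.random.default_rng([int(truth.seed), int(film_index)])
        film = film + truth.noise_sd_mm * rng.standard_normal(film.shape)
    return LandmarkSet(
        left_teardrop=Point2D(*film[0]),
        right_teardrop=Point2D(*film[1]),
        scj=Point2D(*film[2]),
        ps=Point2D(*film[3]),
        rim_points=film[4:],
        side=truth.side,
        scale_mm_per_unit=1.0,
    )


def simulate_study(
    model: PelvisAnatomyModel,
    truth: SimulationTruth,
    pose_film2_overrides: dict | None = None,
) -> tuple[LandmarkSet, LandmarkSet, SimulationTruth]:
    """Two films of the same cup under different pelvic poses.

    ``pose_film2_overrides`` replaces fields of ``truth`` for the second
    film (typically ``flexion_deg``/``rotation_deg``); the cup truth itself
    is shared. Reproducible under ``truth.seed``.
    """
    truth2 = dataclasses.replace(truth, **(pose_film2_overrides or {}))
    lm1 = project_film(model, truth, film_index=0)
    lm2 = project_film(model, truth2, film_index=1)
    return lm1, lm2, truth
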
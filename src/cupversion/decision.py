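"""Two-film comparison rule resolving anteversion versus retroversion.

A single AP film cannot tell whether the cup is anteverted or retroverted:
the projected ellipse is identical for the two mirror-image 3D normals.
But the standardized version of the *true* normal is a property of the cup
alone, while the ghost candidate's standardized value shifts with the
pelvic pose. Measuring two films taken with different pelvic poses, the
physically correct candidate agrees between films up to measurement error,
and the ghost does not: the smaller inter-film difference identifies the
true sign.

``decide_version`` evaluates the candidate pairings across the two films,
picks the most mutually consistent pair, and labels the cup by the sign of
that pair's mean. When each film's candidates straddle zero (the usual
clinical situation) this is exactly the published rule — compare the
anteversion-assumed difference with the retroversion-assumed difference —
but it remains correct in strongly tilted poses where both of a film's
candidates share a sign and the consistent value migrates between slots.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Literal

import numpy as np

from .errors import InvalidMeasurementError, PoseSeparationWarning
from .measure import CupMeasurement, PoseEstimate

__all__ = ["VersionDecision", "decide_version", "pose_separation_deg"]

Label = Literal["anteverted", "retroverted", "indeterminate"]


@dataclasses.dataclass(frozen=True)
class VersionDecision:
    """Outcome of the two-film comparison.

    delta_ante_deg
        |v1_film1 - v1_film2|, the disagreement under the anteversion
        assumption.
    delta_retro_deg
        ||v2_film1| - |v2_film2||, the disagreement under the retroversion
        assumption (magnitudes, matching how the angles are reported).
    label
        "anteverted", "retroverted", or "indeterminate" when the films do
        not discriminate (near-identical poses, or a winner margin within
        the tie tolerance).
    final_version_deg
        Signed arithmetic mean of the winning candidate pair; None when
        indeterminate.
    pose_separation_deg
        Angle between the two films' estimated 3D pelvic-axis directions;
        None when either measurement carries no pose.
    """

    delta_ante_deg: float
    delta_retro_deg: float
    label: Label
    final_version_deg: float | None
    pose_separation_deg: float | None

    def __post_init__(self) -> None:
        if self.delta_ante_deg < 0.0 or self.delta_retro_deg < 0.0:
            raise ValueError("deltas must be non-negative")
        if self.label == "anteverted" and not self.final_version_deg >= 0.0:
            raise ValueError("anteverted label requires final_version_deg >= 0")
        if self.label == "retroverted" and not self.final_version_deg <= 0.0:
            raise ValueError("retroverted label requires final_version_deg <= 0")


def _axis_direction_3d(pose: PoseEstimate, neutral_axis_angle_deg: float) -> np.ndarray:
    """The film-frame 3D direction of the pelvic axis implied by a pose."""
    phi0 = math.radians(neutral_axis_angle_deg)
    axis = np.array([0.0, -math.cos(phi0), math.sin(phi0)])
    f, r = math.radians(pose.flexion_deg), math.radians(pose.rotation_deg)
    rx = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, math.cos(f), -math.sin(f)],
            [0.0, math.sin(f), math.cos(f)],
        ]
    )
    rz = np.array(
        [
            [math.cos(r), -math.sin(r), 0.0],
            [math.sin(r), math.cos(r), 0.0],
            [0.0, 0.0, 1.0],
        ]
    )
    return rz @ rx @ axis


def pose_separation_deg(
    pose1: PoseEstimate,
    pose2: PoseEstimate,
    neutral_axis_angle_deg: float | None = None,
) -> float:
    """Angle between the two films' estimated 3D pelvic-axis directions.

    The projected axis *direction* alone cannot see flexion differences
    (flexion foreshortens the axis without turning it in-plane), so the
    separation is computed between the 3D axis orientations implied by the
    full pose estimates, using the neutral axis inclination of the default
    anatomy when none is given.
    """
    if neutral_axis_angle_deg is None:
        from .simulate import default_pelvis_model

        neutral_axis_angle_deg = default_pelvis_model().neutral_axis_angle_deg
    u1 = _axis_direction_3d(pose1, neutral_axis_angle_deg)
    u2 = _axis_direction_3d(pose2, neutral_axis_angle_deg)
    return math.degrees(math.acos(float(np.clip(u1 @ u2, -1.0, 1.0))))


def decide_version(
    m1: CupMeasurement,
    m2: CupMeasurement,
    tie_tol_deg: float = 0.1,
    *,
    min_separation_deg: float = 1.0,
    neutral_axis_angle_deg: float | None = None,
) -> VersionDecision:
    """Resolve anteversion versus retroversion from two films' measurements.

    The four cross-film candidate pairs are ranked by their absolute signed
    difference. If the best pair beats the runner-up by more than
    ``tie_tol_deg`` and its mean is larger than ``tie_tol_deg`` in
    magnitude, the label is the sign of that mean and
    ``final_version_deg`` its value; otherwise the films were too similar
    (or the cup too close to zero version) and the outcome is
    "indeterminate" — a first-class result, not an error.

    Warns with :class:`PoseSeparationWarning` when both measurements carry
    pose estimates and the films' pelvic axes differ by less than
    ``min_separation_deg`` (the rule requires genuinely different poses).
    """
    for m in (m1, m2):
        if not (math.isfinite(m.liaw_v1_deg) and math.isfinite(m.liaw_v2_deg)):
            raise InvalidMeasurementError(
                "both measurements must carry finite (v1, v2) candidate pairs"
            )

    delta_ante = abs(m1.liaw_v1_deg - m2.liaw_v1_deg)
    delta_retro = abs(abs(m1.liaw_v2_deg) - abs(m2.liaw_v2_deg))

    pairs = [
        (m1.liaw_v1_deg, m2.liaw_v1_deg),
        (m1.liaw_v2_deg, m2.liaw_v2_deg),
        (m1.liaw_v1_deg, m2.liaw_v2_deg),
        (m1.liaw_v2_deg, m2.liaw_v1_deg),
    ]
    diffs = [abs(a - b) for a, b in pairs]
    order = sorted(range(4), key=diffs.__getitem__)
    best, runner = order[0], order[1]
    margin = diffs[runner] - diffs[best]
    mean = 0.5 * (pairs[best][0] + pairs[best][1])

    separation: float | None = None
    if m1.pose is not None and m2.pose is not None:
        separation = pose_separation_deg(m1.pose, m2.pose, neutral_axis_angle_deg)
        if separation < min_separation_deg:
            warnings.warn(
                f"pelvic poses differ by only {separation:.2f} deg; "
                "the anteversion/retroversion call may be unreliable",
                PoseSeparationWarning,
                stacklevel=2,
            )

    if margin <= tie_tol_deg or abs(mean) <= tie_tol_deg:
        label: Label = "indeterminate"
        final: float | None = None
    else:
        label = "anteverted" if mean > 0.0 else "retroverted"
        final = mean

    return VersionDecision(
        delta_ante_deg=delta_ante,
        delta_retro_deg=delta_retro,
        label=label,
        final_version_deg=final,
        pose_separation_deg=separation,
    )
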
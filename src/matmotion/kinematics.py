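"""Upper-limb forward kinematics and the sensor-placement error model.

Arm segments are rigid links: the upper arm of length ``l_UA`` and the
forearm of length ``l_FA``, each with its proximal→distal axis along the
segment frame's *y*.  With both segments instrumented (TWO_IMUS) the elbow
and hand follow from the two segment orientations expressed in the trunk
frame::

    p_EL = R_T_UA · (0, l_UA, 0)
    p_H  = p_EL + R_T_FA · (0, l_FA, 0)

With a single unit per arm (UPPER_ONLY / FOREARM_ONLY) the elbow is
assumed extended and both links share that unit's orientation,
``p_H = R_T_A · (0, l_UA + l_FA, 0)``.  The hand-position error committed
by that simplification is a chord of the elbow-flexion angle φ::

    ε_UA = l_FA · √(2 − 2·cos φ)      (upper-arm unit)
    ε_FA = l_UA · √(2 − 2·cos φ)      (forearm unit)

The shoulder is the trunk-frame origin of each arm; mat-frame coordinates
add the shoulder anchor and the fused trunk orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .imu_fusion import RotationSeries
from .quaternions import quat_conj, quat_multiply, quat_rotate

__all__ = [
    "ArmModel",
    "Placement",
    "ArmPose",
    "segment_in_trunk",
    "full_arm_fk",
    "simplified_fk",
    "placement_error",
    "elbow_angle",
    "to_mat_frame",
]


class Placement(str, Enum):
    TWO_IMUS = "two_imus"
    UPPER_ONLY = "upper_only"
    FOREARM_ONLY = "forearm_only"


@dataclass
class ArmModel:
    """Rigid two-link arm: segment lengths in metres, y proximal→distal."""

    side: str = "right"  # "left" or "right"
    l_ua: float = 0.07
    l_fa: float = 0.07

    def __post_init__(self) -> None:
        if self.l_ua <= 0 or self.l_fa <= 0:
            raise ValueError("segment lengths must be positive")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def l_ua_vec(self) -> np.ndarray:
        return np.array([0.0, self.l_ua, 0.0])

    @property
    def l_fa_vec(self) -> np.ndarray:
        return np.array([0.0, self.l_fa, 0.0])


@dataclass
class ArmPose:
    """Elbow and hand position series (metres) in TRUNK or MAT frame."""

    t: np.ndarray
    p_el: np.ndarray  # (n, 3)
    p_h: np.ndarray  # (n, 3)
    frame: str = "TRUNK"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p_el = np.atleast_2d(np.asarray(self.p_el, dtype=float))
        self.p_h = np.atleast_2d(np.asarray(self.p_h, dtype=float))

    def __len__(self) -> int:
        return len(self.t)


def segment_in_trunk(trunk: RotationSeries, seg: RotationSeries, tol: float = 0.010) -> RotationSeries:
    """Express a segment orientation in the trunk frame: R_T_A = R_T_E · R_E_A.

    Both series must share the parent frame; pairing is nearest-sample
    within ``tol`` seconds.
    """
    if trunk.frame_to != seg.frame_to:
        raise ValueError(f"frame mismatch: {trunk.frame_to} vs {seg.frame_to}")
    idx = trunk.nearest_indices(seg.t, tol)
    q = quat_multiply(quat_conj(trunk.q[idx]), seg.q)
    return RotationSeries(seg.t, q, frame_from=seg.frame_from, frame_to=trunk.frame_from)


def full_arm_fk(r_t_ua: RotationSeries, r_t_fa: RotationSeries, model: ArmModel) -> ArmPose:
    """Two-IMU forward kinematics (shoulder at the trunk-frame origin)."""
    p_el = quat_rotate(r_t_ua.q, model.l_ua_vec)
    p_h = p_el + quat_rotate(r_t_fa.q, model.l_fa_vec)
    return ArmPose(r_t_ua.t, p_el, p_h, frame="TRUNK")


def simplified_fk(r_t_a: RotationSeries, model: ArmModel, placement: Placement) -> ArmPose:
    """Single-IMU forward kinematics: both links share one orientation."""
    if placement == Placement.TWO_IMUS:
        raise ValueError("simplified FK applies to single-IMU placements only")
    p_el = quat_rotate(r_t_a.q, model.l_ua_vec)
    p_h = quat_rotate(r_t_a.q, model.l_ua_vec + model.l_fa_vec)
    return ArmPose(r_t_a.t, p_el, p_h, frame="TRUNK")


def placement_error(phi: np.ndarray | float, model: ArmModel, placement: Placement) -> np.ndarray | float:
    """Analytic hand-position error of a single-IMU placement at elbow
    flexion ``phi`` ∈ [0, π] (chord-length law)."""
    phi_arr = np.asarray(phi, dtype=float)
    if np.any(phi_arr < -1e-12) or np.any(phi_arr > np.pi + 1e-12):
        raise ValueError("phi must lie in [0, pi]")
    chord = np.sqrt(np.maximum(2.0 - 2.0 * np.cos(phi_arr), 0.0))
    if placement == Placement.UPPER_ONLY:
        out = model.l_fa * chord
    elif placement == Placement.FOREARM_ONLY:
        out = model.l_ua * chord
    else:
        raise ValueError("placement error applies to single-IMU placements only")
    return float(out) if np.isscalar(phi) else out


def elbow_angle(r_t_ua: RotationSeries, r_t_fa: RotationSeries, tol: float = 0.010) -> np.ndarray:
    """Elbow flexion φ: angle between the two segments' distal (y) axes, [0, π]."""
    idx = r_t_ua.nearest_indices(r_t_fa.t, tol)
    y = np.array([0.0, 1.0, 0.0])
    y_ua = quat_rotate(r_t_ua.q[idx], y)
    y_fa = quat_rotate(r_t_fa.q, y)
    c = np.clip(np.einsum("ij,ij->i", y_ua, y_fa), -1.0, 1.0)
    return np.arccos(c)


def to_mat_frame(
    pose: ArmPose,
    shoulder: np.ndarray,
    trunk_fused: RotationSeries,
    tol: float = 0.010,
) -> ArmPose:
    """Express an arm pose in the mat frame: p_MAT = shoulder + R_MAT_T · p_TRUNK.

    ``shoulder`` is either a single (3,) anchor or an (n, 3) series in mat
    metres; the fused trunk orientation supplies R_MAT_T per sample.
    """
    if pose.frame != "TRUNK":
        raise ValueError("pose must be in the TRUNK frame")
    shoulder = np.asarray(shoulder, dtype=float)
    idx = trunk_fused.nearest_indices(pose.t, tol)
    q = trunk_fused.q[idx]
    p_el = shoulder + quat_rotate(q, pose.p_el)
    p_h = shoulder + quat_rotate(q, pose.p_h)
    return ArmPose(pose.t, p_el, p_h, frame="MAT")
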
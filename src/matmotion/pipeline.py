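"""End-to-end processing: session bundle → landmarks, kinematics, metrics.

Stage order mirrors the measurement method: pressure frames are cleaned
and turned into COP / trunk-orientation / shoulder / head landmarks; each
IMU stream is fused into an orientation series and expressed in the mat
reference frame; the trunk orientation is yaw-corrected against the
imprint; arm forward kinematics produces elbow/hand trajectories in the
trunk and mat frames under the configured sensor placement; and the
motor-pattern parameter suite is evaluated on the hand trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import motor_metrics as mm
from . import pressure_image as pi
from .config import Config
from .imu_fusion import (
    RotationSeries,
    dynamic_acceleration,
    estimate_orientation,
    fuse_trunk_series,
    to_reference,
)
from .kinematics import (
    ArmModel,
    ArmPose,
    Placement,
    full_arm_fk,
    segment_in_trunk,
    simplified_fk,
    to_mat_frame,
)
from .quaternions import quat_rotate, quat_to_matrix
from .session_io import SessionBundle

__all__ = ["PressureLandmarks", "PipelineResult", "extract_landmarks", "process_session"]


@dataclass
class PressureLandmarks:
    """Per-frame pressure-derived landmark series (30 Hz)."""

    t: np.ndarray
    cop: np.ndarray  # (n, 2) NaN when no contact
    angle: np.ndarray  # (n,) trunk imprint angle [rad]
    trust: np.ndarray  # (n,)
    shoulders: np.ndarray  # (n, 2, 3) [left, right]
    head: np.ndarray  # (n, 2) NaN when absent


@dataclass
class PipelineResult:
    config: Config
    landmarks: PressureLandmarks
    rotations_ref: dict  # label -> RotationSeries in REF frame
    trunk_fused: RotationSeries
    arm_poses_trunk: dict  # arm -> ArmPose (TRUNK)
    arm_poses_mat: dict  # arm -> ArmPose (MAT)
    hand_velocity: dict  # arm -> (n, 3) gyro-based v_H in REF frame
    intervals: dict  # arm -> list[MovementInterval]
    reports: dict  # arm -> MetricsReport

    def report(self, arm: str = "right") -> mm.MetricsReport:
        return self.reports[arm]


def extract_landmarks(
    bundle: SessionBundle,
    cfg: Config,
    trunk_ref: Optional[RotationSeries] = None,
) -> PressureLandmarks:
    """Run the pressure stack over every frame of the session.

    ``trunk_ref`` (trunk orientation in the mat frame) supplies the
    cranial-direction disambiguation and roll adjustment for shoulder
    placement; without it, supine identity orientation is assumed.
    """
    trust_model = pi.TrustModel(cfg.trust_load_ref, cfg.trust_length_ref, cfg.trust_dist_ref)
    geom = pi.ShoulderGeometry(
        cfg.shoulder_half_separation, cfg.shoulder_cranial_offset, cfg.shoulder_height
    )
    bias = bundle.meta.pressure_bias
    n = len(bundle.pressure)
    cop = np.full((n, 2), np.nan)
    angle = np.full(n, np.nan)
    trust = np.zeros(n)
    shoulders = np.full((n, 2, 3), np.nan)
    head = np.full((n, 2), np.nan)
    prev_head: Optional[np.ndarray] = None
    eye = np.eye(3)
    for k in range(n):
        frame = pi.PressureFrame(bundle.pressure.t[k], bundle.pressure.frames[k])
        if bias is not None:
            frame = pi.remove_bias(frame, pi.PressureFrame(frame.t, bias))
        frame = pi.suppress_noise(frame, cfg.pixel_threshold)
        try:
            c = pi.center_of_pressure(frame)
        except pi.NoContactError:
            continue
        cop[k] = c
        fine = pi.upsample(frame)
        try:
            imprint = pi.trunk_imprint(fine, c, cfg.trunk_radius, cfg.min_area, cfg.min_load)
        except pi.NoContactError:
            continue
        a, tr = pi.imprint_orientation(imprint, fine, trust_model)
        angle[k] = a
        trust[k] = tr
        if trunk_ref is not None:
            idx = trunk_ref.nearest_indices(frame.t, tol=0.05)[0]
            R = quat_to_matrix(trunk_ref.q[idx])
        else:
            R = eye
        sh, _ = pi.detect_shoulders(imprint, fine, a, R, geom, trust=tr)
        shoulders[k] = sh
        h = pi.detect_head(fine, sh, prev_head, dt=1.0 / 30.0)
        if h is not None:
            head[k] = h
            prev_head = h
    return PressureLandmarks(bundle.pressure.t.copy(), cop, angle, trust, shoulders, head)


def _interp_series(t_src: np.ndarray, y: np.ndarray, t_dst: np.ndarray) -> np.ndarray:
    ok = np.all(np.isfinite(y.reshape(len(y), -1)), axis=1)
    if ok.sum() < 2:
        raise ValueError("too few valid landmark samples")
    flat = y[ok].reshape(ok.sum(), -1)
    out = np.column_stack(
        [np.interp(t_dst, t_src[ok], flat[:, j]) for j in range(flat.shape[1])]
    )
    return out.reshape((len(t_dst),) + y.shape[1:])


def process_session(bundle: SessionBundle, cfg: Config | None = None) -> PipelineResult:
    """Full pipeline on one session bundle."""
    cfg = cfg or Config()
    placement = Placement(cfg.placement)
    l_ua = bundle.meta.l_ua or cfg.l_ua
    l_fa = bundle.meta.l_fa or cfg.l_fa

    # ---- orientation estimation ----
    est_e = {}
    for label, s in bundle.imu.items():
        est_e[label] = estimate_orientation(
            s.t, s.gyro, s.acc, s.mag, cfg.ukf_params(label), frame_from=label
        )
    if "REF" in est_e:
        rot_ref = {
            label: to_reference(est_e[label], est_e["REF"])
            for label in est_e
            if label != "REF"
        }
    else:  # no corner unit: E doubles as the mat frame
        rot_ref = {
            label: RotationSeries(s.t, s.q, frame_from=s.frame_from, frame_to="REF", att_cov=s.att_cov)
            for label, s in est_e.items()
        }
    if "TRUNK" not in rot_ref:
        raise ValueError("session carries no trunk IMU stream")

    # ---- pressure landmarks and trunk fusion ----
    landmarks = extract_landmarks(bundle, cfg, trunk_ref=rot_ref["TRUNK"])
    trunk_fused = fuse_trunk_series(
        rot_ref["TRUNK"], landmarks.t, landmarks.angle, landmarks.trust
    )

    # ---- arm kinematics ----
    model = {"left": ArmModel("left", l_ua, l_fa), "right": ArmModel("right", l_ua, l_fa)}
    seg_labels = {
        "left": ("UA_L", "FA_L"),
        "right": ("UA_R", "FA_R"),
    }
    arm_poses_trunk: dict[str, ArmPose] = {}
    arm_poses_mat: dict[str, ArmPose] = {}
    hand_vel: dict[str, np.ndarray] = {}
    intervals: dict[str, list] = {}
    reports: dict[str, mm.MetricsReport] = {}
    for arm, (ua_lab, fa_lab) in seg_labels.items():
        have_ua = ua_lab in rot_ref
        have_fa = fa_lab in rot_ref
        if placement == Placement.TWO_IMUS and have_ua and have_fa:
            r_t_ua = segment_in_trunk(trunk_fused, rot_ref[ua_lab])
            r_t_fa = segment_in_trunk(trunk_fused, rot_ref[fa_lab])
            pose = full_arm_fk(r_t_ua, r_t_fa, model[arm])
        elif placement == Placement.UPPER_ONLY and have_ua:
            r_t_ua = segment_in_trunk(trunk_fused, rot_ref[ua_lab])
            pose = simplified_fk(r_t_ua, model[arm], placement)
            r_t_fa = r_t_ua
        elif placement == Placement.FOREARM_ONLY and have_fa:
            r_t_fa = segment_in_trunk(trunk_fused, rot_ref[fa_lab])
            pose = simplified_fk(r_t_fa, model[arm], placement)
            r_t_ua = r_t_fa
        else:
            continue
        arm_poses_trunk[arm] = pose

        # shoulder anchor series on the 100 Hz timeline
        side = 0 if arm == "left" else 1
        try:
            anchor = _interp_series(landmarks.t, landmarks.shoulders[:, side], pose.t)
        except ValueError:
            anchor = None
        if anchor is not None:
            arm_poses_mat[arm] = to_mat_frame(pose, anchor, trunk_fused, tol=0.05)

        # gyro-based hand velocity (Eq of the angular-velocity chain)
        fs = 1.0 / np.median(np.diff(pose.t))
        q_ref_t = trunk_fused.q
        r_ua_vec = quat_rotate(q_ref_t, pose.p_el)
        r_fa_vec = quat_rotate(q_ref_t, pose.p_h - pose.p_el)
        if placement == Placement.TWO_IMUS:
            w_ua = quat_rotate(rot_ref[ua_lab].q, bundle.imu[ua_lab].gyro)
            w_fa = quat_rotate(rot_ref[fa_lab].q, bundle.imu[fa_lab].gyro)
            v_h = mm.hand_velocity_gyro(w_ua, w_fa, r_ua_vec, r_fa_vec)
        else:
            lab = ua_lab if placement == Placement.UPPER_ONLY else fa_lab
            w = quat_rotate(rot_ref[lab].q, bundle.imu[lab].gyro)
            v_h = mm.hand_velocity_forearm_only(w, r_ua_vec + r_fa_vec)
        v_h = mm.lowpass(v_h, fs, cfg.lowpass_fc)
        hand_vel[arm] = v_h
        speed = np.linalg.norm(v_h, axis=1)
        ivals = mm.segment_movements(pose.t, speed, cfg.v_on, cfg.v_off, cfg.d_min)
        intervals[arm] = ivals

        reports[arm] = _arm_report(
            arm, pose, arm_poses_mat.get(arm), v_h, ivals, bundle, rot_ref,
            fa_lab if have_fa else ua_lab, model[arm], placement, cfg, fs,
        )

    return PipelineResult(
        cfg, landmarks, rot_ref, trunk_fused, arm_poses_trunk, arm_poses_mat,
        hand_vel, intervals, reports,
    )


def _arm_report(
    arm: str,
    pose: ArmPose,
    pose_mat: Optional[ArmPose],
    v_h: np.ndarray,
    ivals: list,
    bundle: SessionBundle,
    rot_ref: dict,
    acc_label: str,
    model: ArmModel,
    placement: Placement,
    cfg: Config,
    fs: float,
) -> mm.MetricsReport:
    rep = mm.MetricsReport(placement=placement.value)
    rep.n_movement_intervals = len(ivals)
    hand_f = mm.lowpass(pose.p_h, fs, cfg.lowpass_fc)

    if ivals:
        a_dyn = dynamic_acceleration(bundle.imu[acc_label].acc, rot_ref[acc_label])
        a_dyn = mm.lowpass(a_dyn, fs, cfg.lowpass_fc)
        rep.rms_acc, rep.rms_jerk, rep.norm_mean_abs_jerk = mm.jerk_metrics(
            pose.t, a_dyn, ivals
        )
        sals = []
        for iv in ivals:
            try:
                sals.append(mm.sal(v_h[iv.i0 : iv.i1], fs, cfg.sal_wc))
            except ValueError:
                continue
        if sals:
            rep.sal_mean = float(np.mean(sals))
            rep.sal_sd = float(np.std(sals))
    try:
        rep.norm_ws_area, _ = mm.workspace_area(hand_f, model, placement)
        r = (
            mm.fit_sphere_radius(hand_f)
            if placement == Placement.TWO_IMUS
            else model.l_ua + model.l_fa
        )
        rep.norm_ws_volume = mm.workspace_volume(hand_f, r)
    except ValueError:
        pass
    if pose_mat is not None:
        hand_mat = mm.lowpass(pose_mat.p_h, fs, cfg.lowpass_fc)
        try:
            rep.reach_concave, rep.reach_convex = mm.reachable_volume(hand_mat)
        except ValueError:
            pass
        rep.travelled_path = mm.travelled_path(hand_mat)
        rep.average_speed = mm.average_speed(
            rep.travelled_path, pose.t[-1] - pose.t[0]
        )
    rep.insufficient_data = rep.travelled_path is None and not ivals
    return rep
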
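"""Articulated-doll session simulator with exact ground truth.

Emulates a supine newborn-sized body on the pressure mat: elliptical
trunk and head imprints, corkscrew trunk rolls about the cranial–caudal
axis, and spontaneous minimum-jerk reach-to-grasp arm movements at
roughly 13 cm/s average hand speed.  Every sensor stream the real rig
produces is synthesized — six IMUs (gyro/accelerometer/magnetometer with
white noise and a random-walk gyro bias) at 100 Hz and the 55 × 32
pressure frames at 30 Hz — alongside the exact segment orientations and
landmark trajectories, so every pipeline stage can be validated without
any recorded data.

All randomness flows from a single seed; identical seeds give identical
sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .imu_fusion import GRAVITY, RotationSeries
from .quaternions import (
    matrix_to_quat,
    quat_conj,
    quat_from_rotvec,
    quat_multiply,
    quat_normalize,
    quat_rotate,
    quat_to_matrix,
    quat_to_rotvec,
)
from .pressure_image import MAT_LENGTH_M, MAT_WIDTH_M, RAW_SHAPE, pixel_centers
from .session_io import ImuStream, MarkerStream, PressureStream, SessionBundle, SessionMeta

FS_IMU = 100.0
FS_PRESSURE = 30.0
MAG_DIP = np.deg2rad(60.0)
MAG_E = np.array([0.0, np.cos(MAG_DIP), -np.sin(MAG_DIP)])  # Earth field in E

__all__ = [
    "DollModel",
    "NoiseParams",
    "Rest",
    "TrunkRoll",
    "Reach",
    "MotionScript",
    "standard_script",
    "GroundTruth",
    "arm_trajectory",
    "two_link_ik",
    "synthesize_imu",
    "render_pressure",
    "simulate_session",
]


@dataclass
class DollModel:
    """Preterm-newborn-scale doll geometry (metres)."""

    trunk_semi_axes: tuple[float, float] = (0.12, 0.06)  # (along y, across x)
    head_semi_axes: tuple[float, float] = (0.05, 0.045)
    l_ua: float = 0.07
    l_fa: float = 0.07
    shoulder_half_separation: float = 0.06
    shoulder_cranial_offset: float = 0.10  # from trunk centre toward head
    trunk_height: float = 0.05  # trunk-centre height above the mat, supine
    neck_gap: float = 0.02
    trunk_weight: float = 0.7  # load share trunk vs head
    head_weight: float = 0.3
    trunk_center_xy: tuple[float, float] = (MAT_WIDTH_M / 2, 0.35)
    trunk_peak_load: float = 60.0  # device units at the imprint centre
    head_peak_load: float = 45.0
    mount_rotations: dict = field(default_factory=dict)  # label -> (3,3)

    def __post_init__(self) -> None:
        if min(self.trunk_semi_axes + self.head_semi_axes) <= 0:
            raise ValueError("ellipse semi-axes must be positive")
        if self.l_ua <= 0 or self.l_fa <= 0:
            raise ValueError("segment lengths must be positive")

    @property
    def reach_max(self) -> float:
        return self.l_ua + self.l_fa

    def shoulder_offset(self, side: str) -> np.ndarray:
        """Shoulder position in the trunk frame (origin at trunk centre);
        baby-left is the +x side."""
        sx = self.shoulder_half_separation if side == "left" else -self.shoulder_half_separation
        return np.array([sx, self.shoulder_cranial_offset, 0.0])

    def head_offset(self) -> np.ndarray:
        y = self.trunk_semi_axes[0] + self.neck_gap + self.head_semi_axes[0]
        return np.array([0.0, y, 0.0])


@dataclass
class NoiseParams:
    gyro_noise_std: float = 0.005  # rad/s per sample
    gyro_bias_walk_std: float = 1e-5  # rad/s per step
    gyro_bias_init_std: float = 0.002  # rad/s
    acc_noise_std: float = 0.05  # m/s^2
    mag_noise_std: float = 0.01  # unit field
    pressure_noise_std: float = 0.5  # device units
    pressure_bias_scale: float = 8.0  # device units

    @classmethod
    def zero(cls) -> "NoiseParams":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


# ---------------------------------------------------------------------------
# Motion script


@dataclass
class Rest:
    duration: float


@dataclass
class TrunkRoll:
    """Smooth roll about the cranial–caudal axis to a target angle [rad]."""

    target: float
    duration: float


@dataclass
class Reach:
    """Minimum-jerk hand displacement in the trunk frame."""

    arm: str  # "left" | "right"
    direction: tuple[float, float, float]
    amplitude: float
    duration: float


Primitive = Union[Rest, TrunkRoll, Reach]


@dataclass
class MotionScript:
    primitives: list
    seed: int = 0

    def __post_init__(self) -> None:
        for p in self.primitives:
            if p.duration <= 0:
                raise ValueError("primitive durations must be positive")

    @property
    def duration(self) -> float:
        return float(sum(p.duration for p in self.primitives))


def standard_script(
    duration: float = 60.0,
    n_reaches: int = 50,
    seed: int = 0,
    reach_amplitude: float = 0.091,
    reach_duration: float = 0.7,
    roll_target: float = np.deg2rad(40.0),
) -> MotionScript:
    """The study-condition script: corkscrew trunk rolls plus paired
    out-and-back minimum-jerk reaches with ≈ 0.13 m/s mean hand speed
    (amplitude / duration = 0.091 m / 0.7 s)."""
    rng = np.random.default_rng(seed)
    prims: list = []
    n_pairs = n_reaches // 2
    extra = n_reaches - 2 * n_pairs
    blocks: list[list] = []
    rest_hand = {
        "left": np.array([0.02, 0.06, 0.10]),
        "right": np.array([-0.02, 0.06, 0.10]),
    }
    reach_max = 0.98 * 0.14  # default doll arm length guard

    def draw_dir(arm: str) -> tuple[float, float, float]:
        # ventrally biased direction whose full-amplitude target stays
        # inside the reachable sphere (no clamping, so the scripted
        # amplitude and mean speed are realized exactly)
        for _ in range(500):
            d = rng.normal(size=3)
            d[2] = abs(d[2]) + 0.5
            d /= np.linalg.norm(d)
            target = rest_hand[arm] + d * reach_amplitude
            if 0.05 <= np.linalg.norm(target) <= reach_max:
                return tuple(d)
        raise RuntimeError("could not draw a reachable direction")

    for k in range(n_pairs):
        arm = "right" if k % 2 == 0 else "left"
        d = draw_dir(arm)
        out = Reach(arm, d, reach_amplitude, reach_duration)
        back = Reach(arm, tuple(-np.asarray(d)), reach_amplitude, reach_duration)
        blocks.append([out, Rest(0.4), back])
    if extra:
        blocks.append([Reach("right", draw_dir("right"), reach_amplitude, reach_duration)])
    # corkscrew: roll to the side and back, twice across the session
    rolls = [
        [TrunkRoll(roll_target, 2.0)],
        [TrunkRoll(0.0, 2.0)],
        [TrunkRoll(-roll_target, 2.0)],
        [TrunkRoll(0.0, 2.0)],
    ]
    seq: list[list] = []
    for i, b in enumerate(blocks):
        seq.append(b)
        if i in (len(blocks) // 4, len(blocks) // 2, 3 * len(blocks) // 4, len(blocks) - 1):
            if rolls:
                seq.append(rolls.pop(0))
    flat: list = []
    for b in seq:
        flat.extend(b)
    busy = sum(p.duration for p in flat)
    n_gaps = len(seq) + 1
    rest = max((duration - busy) / n_gaps, 0.05)
    prims = [Rest(rest)]
    for b in seq:
        prims.extend(b)
        prims.append(Rest(rest))
    return MotionScript(prims, seed=seed)


def _minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk position profile s(τ), τ ∈ [0, 1]."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


# ---------------------------------------------------------------------------
# Inverse kinematics


def two_link_ik(
    p_hand: np.ndarray, l_ua: float, l_fa: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two-link inverse kinematics of hand positions relative to the
    shoulder (trunk frame).

    Returns per-sample quaternions (T←UA, T←FA).  The elbow flexion
    follows from the chord length; the arm plane is spanned by the reach
    direction and the trunk dorsal–ventral axis (elbow kept caudal), which
    keeps orientations continuous for ventral-side movements.
    """
    p = np.atleast_2d(np.asarray(p_hand, dtype=float))
    d = np.linalg.norm(p, axis=1)
    if np.any(d > l_ua + l_fa + 1e-9):
        raise ValueError("unreachable hand target beyond full arm length")
    d = np.clip(d, 1e-6, l_ua + l_fa)
    u = p / d[:, None]
    cos_alpha = np.clip((d**2 + l_ua**2 - l_fa**2) / (2 * d * l_ua), -1.0, 1.0)
    alpha = np.arccos(cos_alpha)
    zref = np.array([0.0, 0.0, 1.0])
    n = np.cross(u, zref)
    nn = np.linalg.norm(n, axis=1)
    bad = nn < 1e-8
    if np.any(bad):
        n[bad] = np.cross(u[bad], np.array([1.0, 0.0, 0.0]))
        nn[bad] = np.linalg.norm(n[bad], axis=1)
    n = n / nn[:, None]
    # upper-arm distal axis: reach direction rotated by alpha about n
    q_alpha = quat_from_rotvec(n * alpha[:, None])
    y_ua = quat_rotate(q_alpha, u)
    p_el = y_ua * l_ua
    y_fa = (p - p_el) / l_fa
    y_fa /= np.linalg.norm(y_fa, axis=1, keepdims=True)

    def frame_quat(y_axis):
        z_axis = n - np.einsum("ij,ij->i", n, y_axis)[:, None] * y_axis
        z_axis /= np.linalg.norm(z_axis, axis=1, keepdims=True)
        x_axis = np.cross(y_axis, z_axis)
        R = np.stack([x_axis, y_axis, z_axis], axis=2)  # columns = segment axes
        return matrix_to_quat(R)

    return frame_quat(y_ua), frame_quat(y_fa)


def arm_trajectory(
    primitive: Reach, model: DollModel, start: np.ndarray, fs: float = FS_IMU
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Hand path and segment orientations of one minimum-jerk reach.

    Returns ``(p_hand (n,3), q_t_ua (n,4), q_t_fa (n,4))`` at ``fs`` Hz,
    hand positions relative to the shoulder in the trunk frame.
    """
    if primitive.amplitude > model.reach_max:
        raise ValueError("reach amplitude exceeds arm length")
    n = max(int(round(primitive.duration * fs)), 2)
    tau = np.arange(n) / (n - 1)
    disp = np.asarray(primitive.direction, dtype=float)
    disp = disp / np.linalg.norm(disp) * primitive.amplitude
    target = np.asarray(start, dtype=float) + disp
    tn = np.linalg.norm(target)
    if tn > 0.98 * model.reach_max:
        target = target / tn * 0.98 * model.reach_max
    if tn < 0.02:
        raise ValueError("reach target collapses onto the shoulder")
    p = start[None, :] + _minimum_jerk(tau)[:, None] * (target - start)[None, :]
    q_ua, q_fa = two_link_ik(p, model.l_ua, model.l_fa)
    return p, q_ua, q_fa


# ---------------------------------------------------------------------------
# Ground truth container


@dataclass
class GroundTruth:
    """Exact simulator state sampled on the 100 Hz IMU timeline."""

    t: np.ndarray
    roll: np.ndarray  # trunk roll angle [rad]
    q_e_t: np.ndarray  # (n, 4) E←T
    q_e_seg: dict  # label -> (n, 4) E←segment for UA_L/UA_R/FA_L/FA_R
    q_t_seg: dict  # label -> (n, 4) T←segment
    p_hand: dict  # arm -> (n, 3) hand rel. shoulder, trunk frame
    p_elbow: dict  # arm -> (n, 3)
    gyro_world: dict  # label -> (n, 3) true angular velocity in E
    hand_world: dict  # arm -> (n, 3) hand in mat frame
    shoulders_world: np.ndarray  # (n, 2, 3) [left, right]
    head_world: np.ndarray  # (n, 2) head centre (x, y)
    cop_world: np.ndarray  # (n, 2) contact-model COP (x, y)
    intervals: list  # (start, end, arm) movement event log
    elbow_angle: dict  # arm -> (n,)


# ---------------------------------------------------------------------------
# Sensor synthesis


def _body_rates(q: np.ndarray, fs: float) -> np.ndarray:
    """Body-frame angular velocity from a quaternion series by the
    logarithmic-map increment: w[k] ≈ log(q_k⁻¹ ⊗ q_{k+1}) · fs."""
    inc = quat_to_rotvec(quat_multiply(quat_conj(q[:-1]), q[1:])) * fs
    return np.vstack([inc, inc[-1:]])


def synthesize_imu(
    t: np.ndarray,
    q_e_s: np.ndarray,
    pos_world: Optional[np.ndarray],
    noise: NoiseParams,
    rng: np.random.Generator,
) -> ImuStream:
    """Synthesize one IMU stream from its true orientation series.

    Gyro = body rates (+ random-walk bias + white noise); specific force
    = Rᵀ(a_lin − g_E) with the linear acceleration from double
    differentiation of the sensor's world position; magnetometer = Rᵀ of
    the Earth field direction.
    """
    n = len(t)
    fs = 1.0 / (t[1] - t[0])
    w = _body_rates(q_e_s, fs)
    g_e = np.array([0.0, 0.0, -GRAVITY])
    if pos_world is None:
        a_lin = np.zeros((n, 3))
    else:
        a_lin = np.gradient(np.gradient(pos_world, t, axis=0), t, axis=0)
    q_inv = quat_conj(q_e_s)
    acc = quat_rotate(q_inv, a_lin - g_e)
    mag = quat_rotate(q_inv, MAG_E)
    bias0 = rng.normal(0.0, noise.gyro_bias_init_std, 3) if noise.gyro_bias_init_std else np.zeros(3)
    if noise.gyro_bias_walk_std:
        walk = np.cumsum(rng.normal(0.0, noise.gyro_bias_walk_std, (n, 3)), axis=0)
    else:
        walk = np.zeros((n, 3))
    gyro = w + bias0 + walk
    if noise.gyro_noise_std:
        gyro = gyro + rng.normal(0.0, noise.gyro_noise_std, (n, 3))
    if noise.acc_noise_std:
        acc = acc + rng.normal(0.0, noise.acc_noise_std, (n, 3))
    if noise.mag_noise_std:
        mag = mag + rng.normal(0.0, noise.mag_noise_std, (n, 3))
    return ImuStream(t, gyro, acc, mag)


# ---------------------------------------------------------------------------
# Pressure rendering


def _contact_shift(roll: float, doll: DollModel) -> float:
    """Lateral contact-patch shift (m) of the trunk imprint under roll;
    load moves toward the side that rotates down onto the mat."""
    return 0.5 * doll.trunk_height * np.sin(roll)


def render_pressure(
    doll: DollModel,
    roll: float = 0.0,
    trunk_xy: Optional[np.ndarray] = None,
    yaw: float = 0.0,
    on_mat: bool = True,
) -> np.ndarray:
    """Render one raw 55 × 32 pressure frame of the doll's contact load.

    Trunk and head appear as elliptical paraboloid load patches under
    their projected positions; rolling shifts the trunk patch laterally
    and narrows it by cos(roll) while its peak load grows to conserve
    total weight.  Returns the noiseless grid (device units).
    """
    grid = np.zeros(RAW_SHAPE)
    if not on_mat:
        return grid
    c = np.asarray(trunk_xy if trunk_xy is not None else doll.trunk_center_xy, dtype=float)
    ys, xs = pixel_centers(RAW_SHAPE)
    X, Y = np.meshgrid(xs, ys)  # (55, 32)
    axis = np.array([np.sin(yaw), np.cos(yaw)])
    perp = np.array([np.cos(yaw), -np.sin(yaw)])
    width_factor = max(np.cos(roll), 0.35)
    shift = _contact_shift(roll, doll)

    def bump(center, a, b, peak):
        u = (X - center[0]) * axis[0] + (Y - center[1]) * axis[1]
        v = (X - center[0]) * perp[0] + (Y - center[1]) * perp[1]
        r2 = (u / a) ** 2 + (v / b) ** 2
        return peak * np.maximum(1.0 - r2, 0.0)

    trunk_c = c + shift * perp
    a_t, b_t = doll.trunk_semi_axes
    grid += bump(trunk_c, a_t, b_t * width_factor, doll.trunk_peak_load / width_factor)
    head_c = c + doll.head_offset()[1] * axis
    a_h, b_h = doll.head_semi_axes
    grid += bump(head_c, a_h, b_h, doll.head_peak_load)
    return grid


def _model_cop(doll: DollModel, roll: float, trunk_xy: np.ndarray, yaw: float) -> np.ndarray:
    """Analytic COP of the contact model (load-weighted patch centres)."""
    axis = np.array([np.sin(yaw), np.cos(yaw)])
    perp = np.array([np.cos(yaw), -np.sin(yaw)])
    width_factor = max(np.cos(roll), 0.35)
    a_t, b_t = doll.trunk_semi_axes
    a_h, b_h = doll.head_semi_axes
    # integral of a paraboloid bump = peak * pi * a * b / 2
    w_t = (doll.trunk_peak_load / width_factor) * a_t * (b_t * width_factor)
    w_h = doll.head_peak_load * a_h * b_h
    trunk_c = trunk_xy + _contact_shift(roll, doll) * perp
    head_c = trunk_xy + doll.head_offset()[1] * axis
    return (w_t * trunk_c + w_h * head_c) / (w_t + w_h)


def _pressure_bias(rng: np.random.Generator, scale: float) -> np.ndarray:
    """Smooth synthetic per-module offset field (device units)."""
    if scale <= 0:
        return np.zeros(RAW_SHAPE)
    coarse = rng.uniform(0.0, scale, (6, 4))
    reps = (int(np.ceil(RAW_SHAPE[0] / 6)), int(np.ceil(RAW_SHAPE[1] / 4)))
    field_ = np.kron(coarse, np.ones(reps))[: RAW_SHAPE[0], : RAW_SHAPE[1]]
    return field_


# ---------------------------------------------------------------------------
# Session assembly


def _roll_and_arm_timelines(
    script: MotionScript, doll: DollModel, fs: float
) -> tuple[np.ndarray, np.ndarray, dict, dict, dict, list]:
    """Sample the script: returns (t, roll, p_hand, q_t_ua, q_t_fa, events)."""
    n_total = int(round(script.duration * fs)) + 1
    t = np.arange(n_total) / fs
    roll = np.zeros(n_total)
    rest_hand = {
        "left": np.array([0.02, 0.06, 0.10]),
        "right": np.array([-0.02, 0.06, 0.10]),
    }
    p_hand = {arm: np.tile(rest_hand[arm], (n_total, 1)) for arm in ("left", "right")}
    events: list = []
    cursor = 0.0
    roll_now = 0.0
    hand_now = {arm: rest_hand[arm].copy() for arm in ("left", "right")}
    for prim in script.primitives:
        i0 = int(round(cursor * fs))
        i1 = min(int(round((cursor + prim.duration) * fs)), n_total - 1)
        seg = slice(i0, i1 + 1)
        nseg = i1 - i0 + 1
        tau = np.arange(nseg) / max(nseg - 1, 1)
        moved_arm = None
        if isinstance(prim, TrunkRoll):
            roll[seg] = roll_now + _minimum_jerk(tau) * (prim.target - roll_now)
            roll_now = prim.target
        elif isinstance(prim, Reach):
            roll[seg] = roll_now
            p, _, _ = arm_trajectory(prim, doll, hand_now[prim.arm], fs=fs)
            # re-sample the primitive onto this segment's sample count
            src = np.linspace(0, 1, len(p))
            p_seg = np.column_stack([np.interp(tau, src, p[:, j]) for j in range(3)])
            p_hand[prim.arm][seg] = p_seg
            hand_now[prim.arm] = p_seg[-1].copy()
            moved_arm = prim.arm
            events.append((t[i0], t[i1], prim.arm))
        else:  # Rest
            roll[seg] = roll_now
        for arm in ("left", "right"):
            if arm != moved_arm:
                p_hand[arm][seg] = hand_now[arm]
        # hold state through any trailing samples (rounding slack)
        roll[i1:] = roll_now
        for arm in ("left", "right"):
            p_hand[arm][i1:] = hand_now[arm]
        cursor += prim.duration
    q_t_ua = {}
    q_t_fa = {}
    for arm in ("left", "right"):
        q_t_ua[arm], q_t_fa[arm] = two_link_ik(p_hand[arm], doll.l_ua, doll.l_fa)
    return t, roll, p_hand, q_t_ua, q_t_fa, events


def simulate_session(
    doll: DollModel | None = None,
    script: MotionScript | None = None,
    noise: NoiseParams | None = None,
    seed: int = 0,
) -> tuple[SessionBundle, GroundTruth]:
    """Generate a fully labelled synthetic session.

    Deterministic given ``seed``; the returned GroundTruth carries the
    exact orientations, landmark trajectories and the movement event log
    on the 100 Hz timeline, and the SessionBundle the noisy 100 Hz IMU and
    30 Hz pressure streams (including the synthetic bias matrix in meta).
    """
    doll = doll or DollModel()
    script = script or standard_script(seed=seed)
    noise = noise if noise is not None else NoiseParams()
    rng = np.random.default_rng(seed)

    t, roll, p_hand, q_t_ua, q_t_fa, events = _roll_and_arm_timelines(script, doll, FS_IMU)
    n = len(t)
    # trunk orientation: supine base (identity) composed with roll about
    # the cranial-caudal (mat y) axis
    q_e_t = quat_from_rotvec(np.column_stack([np.zeros(n), roll, np.zeros(n)]))
    trunk_center = np.concatenate(
        [np.asarray(doll.trunk_center_xy), [doll.trunk_height]]
    )
    labels = {
        "UA_L": ("left", q_t_ua), "UA_R": ("right", q_t_ua),
        "FA_L": ("left", q_t_fa), "FA_R": ("right", q_t_fa),
    }
    q_e_seg = {}
    q_t_seg = {}
    for label, (arm, src) in labels.items():
        q_t_seg[label] = src[arm]
        q_e_seg[label] = quat_multiply(q_e_t, src[arm])

    shoulders_world = np.empty((n, 2, 3))
    hand_world = {}
    p_elbow = {}
    elbow = {}
    for i, arm in enumerate(("left", "right")):
        off = doll.shoulder_offset(arm)
        sh = trunk_center[None, :] + quat_rotate(q_e_t, off)
        shoulders_world[:, i] = sh
        hand_world[arm] = sh + quat_rotate(q_e_t, p_hand[arm])
        p_el = quat_rotate(q_t_ua[arm], np.array([0.0, doll.l_ua, 0.0]))
        p_elbow[arm] = p_el
        d = np.linalg.norm(p_hand[arm], axis=1)
        cosphi = np.clip(
            (d**2 - doll.l_ua**2 - doll.l_fa**2) / (2 * doll.l_ua * doll.l_fa), -1.0, 1.0
        )
        elbow[arm] = np.arccos(cosphi)

    head_world = np.tile(
        np.asarray(doll.trunk_center_xy) + np.array([0.0, doll.head_offset()[1]]), (n, 1)
    )
    cop_world = np.array(
        [_model_cop(doll, r, np.asarray(doll.trunk_center_xy), 0.0) for r in roll]
    )

    # ---- IMU streams ----
    imu = {}
    imu_pos = {"REF": None, "TRUNK": np.tile(trunk_center, (n, 1))}
    for label, (arm, _) in labels.items():
        sh = shoulders_world[:, 0 if arm == "left" else 1]
        if label.startswith("UA"):
            mid = quat_rotate(q_e_seg[label], np.array([0.0, doll.l_ua / 2, 0.0]))
            imu_pos[label] = sh + mid
        else:
            el = sh + quat_rotate(q_e_seg[label.replace("FA", "UA")], np.array([0.0, doll.l_ua, 0.0]))
            imu_pos[label] = el + quat_rotate(q_e_seg[label], np.array([0.0, doll.l_fa / 2, 0.0]))
    q_identity = np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (n, 1))
    q_units = {"REF": q_identity, "TRUNK": q_e_t, **q_e_seg}
    for label in ("REF", "TRUNK", "UA_L", "UA_R", "FA_L", "FA_R"):
        q_u = q_units[label]
        mount = doll.mount_rotations.get(label)
        if mount is not None:
            q_u = quat_multiply(q_u, np.broadcast_to(matrix_to_quat(np.asarray(mount)), (n, 4)))
        imu[label] = synthesize_imu(t, q_u, imu_pos[label], noise, rng)

    gyro_world = {
        label: quat_rotate(q_units[label], _body_rates(q_units[label], FS_IMU))
        for label in ("TRUNK", "UA_L", "UA_R", "FA_L", "FA_R")
    }

    # ---- pressure frames ----
    n30 = int(np.floor(t[-1] * FS_PRESSURE)) + 1
    t30 = np.arange(n30) / FS_PRESSURE
    idx = np.clip(np.round(t30 * FS_IMU).astype(int), 0, n - 1)
    bias = _pressure_bias(rng, noise.pressure_bias_scale)
    frames = np.empty((n30, *RAW_SHAPE))
    for k, i in enumerate(idx):
        g = render_pressure(doll, roll=roll[i])
        if noise.pressure_noise_std:
            g = g + rng.normal(0.0, noise.pressure_noise_std, RAW_SHAPE)
        frames[k] = np.maximum(g + bias, 0.0)
    pressure = PressureStream(t30, frames)

    meta = SessionMeta(l_ua=doll.l_ua, l_fa=doll.l_fa, pressure_bias=bias)
    # reference marker streams (noise-free), the optical-capture analogue
    markers = {
        "HAND_L": MarkerStream(t, hand_world["left"]),
        "HAND_R": MarkerStream(t, hand_world["right"]),
        "SH_L": MarkerStream(t, shoulders_world[:, 0]),
        "SH_R": MarkerStream(t, shoulders_world[:, 1]),
    }
    bundle = SessionBundle(pressure, imu, markers, meta)
    truth = GroundTruth(
        t=t,
        roll=roll,
        q_e_t=q_e_t,
        q_e_seg=q_e_seg,
        q_t_seg=q_t_seg,
        p_hand={a: p_hand[a] for a in ("left", "right")},
        p_elbow=p_elbow,
        gyro_world=gyro_world,
        hand_world=hand_world,
        shoulders_world=shoulders_world,
        head_world=head_world,
        cop_world=cop_world,
        intervals=events,
        elbow_angle=elbow,
    )
    return bundle, truth
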
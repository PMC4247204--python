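"""Orientation estimation and trunk sensor fusion.

Each wearable unit delivers 100 Hz 3-axis angular velocity, specific force
and magnetic field.  A quaternion error-state unscented Kalman filter
(UKF) fuses them into the unit's orientation w.r.t. the Earth frame *E*
(z up, y along magnetic north's horizontal component, x east).  The state
is the 3-D attitude error about a reference quaternion plus a 3-D gyro
bias; the prediction integrates the bias-corrected gyro, and the update
draws on the gravity direction (accelerometer) and the magnetic field
direction (magnetometer), with the accelerometer down-weighted whenever
the specific-force magnitude departs from 1 g (dynamic-motion guard).

Orientations are then re-expressed in the mattress reference frame (the
corner unit *REF*), and the trunk unit's yaw about the mat normal is
corrected against the pressure-imprint orientation whenever the imprint
trust is high; otherwise the last reliable yaw offset is held.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .quaternions import (
    matrix_to_quat,
    quat_canonical,
    quat_conj,
    quat_from_rotvec,
    quat_multiply,
    quat_normalize,
    quat_rotate,
    quat_to_matrix,
    quat_to_rotvec,
)

GRAVITY = 9.81  # m/s^2
G_VEC = np.array([0.0, 0.0, GRAVITY])

__all__ = [
    "UkfParams",
    "RotationSeries",
    "triad",
    "estimate_orientation",
    "to_reference",
    "TrunkOrientationFuser",
    "fuse_trunk_series",
    "dynamic_acceleration",
]


@dataclass
class UkfParams:
    """Noise/tuning parameters of the attitude UKF (MEMS-grade defaults)."""

    gyro_noise_std: float = 0.005  # rad/s, white, per sample
    gyro_bias_walk_std: float = 1e-5  # rad/s per step random walk
    acc_noise_std: float = 0.05  # m/s^2 per axis
    mag_noise_std: float = 0.01  # unit-field per axis
    alpha: float = 1e-2  # sigma-point spread
    beta: float = 2.0
    kappa: float = 0.0
    dynamic_guard_ms2: float = 0.5  # | |a| - g | beyond which accel is down-weighted
    dynamic_guard_inflation: float = 100.0
    p0_attitude: float = (np.deg2rad(10.0)) ** 2
    p0_bias: float = (0.01) ** 2
    # acquisition watchdog: if the estimate disagrees with the analytic
    # accelerometer/magnetometer attitude by more than ``watchdog_angle``
    # for ``watchdog_steps`` quasi-static samples (leaky count), the
    # attitude is re-acquired from that analytic fix.  The dynamic guard
    # keeps it from firing during genuine movement.
    watchdog_angle: float = np.deg2rad(10.0)
    watchdog_steps: int = 6  # leaky count of (strided) disagreeing checks
    watchdog_stride: int = 5  # evaluate the analytic fix every k-th sample
    # two-stage estimation: bias updates are frozen for a short settling
    # window after start-up, so an initial attitude transient cannot push
    # a spurious value into the bias state
    bias_freeze_time: float = 2.0  # s


@dataclass
class RotationSeries:
    """Time-stamped orientations of ``frame_from`` expressed in ``frame_to``.

    ``q[k]`` (Hamilton, scalar-first) maps ``frame_from`` vectors into
    ``frame_to``: ``v_to = q ⊛ v_from``.  ``att_cov`` optionally carries the
    3×3 attitude-error covariance per sample (rad²).
    """

    t: np.ndarray
    q: np.ndarray
    frame_from: str
    frame_to: str
    att_cov: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q = quat_normalize(np.asarray(self.q, dtype=float))
        if self.q.shape != (len(self.t), 4):
            raise ValueError("q must be (n, 4) matching t")

    def __len__(self) -> int:
        return len(self.t)

    def as_matrices(self) -> np.ndarray:
        return quat_to_matrix(self.q)

    def nearest_indices(self, t_query: np.ndarray, tol: float = 0.010) -> np.ndarray:
        """Indices of the nearest samples; error if any gap exceeds ``tol`` s."""
        t_query = np.atleast_1d(np.asarray(t_query, dtype=float))
        idx = np.searchsorted(self.t, t_query)
        idx = np.clip(idx, 1, len(self.t) - 1)
        left = idx - 1
        choose_left = np.abs(t_query - self.t[left]) <= np.abs(self.t[idx] - t_query)
        idx = np.where(choose_left, left, idx)
        if np.any(np.abs(self.t[idx] - t_query) > tol):
            raise ValueError("no sample within pairing tolerance")
        return idx


def triad(acc: np.ndarray, mag: np.ndarray) -> np.ndarray:
    """Analytic accelerometer/magnetometer orientation (quaternion E←S).

    The static solution: sensor-frame up from the specific force, magnetic
    north from the field's horizontal component.
    """
    a = np.asarray(acc, dtype=float)
    m = np.asarray(mag, dtype=float)
    up_s = a / np.linalg.norm(a)
    mh = m - (m @ up_s) * up_s
    nh = np.linalg.norm(mh)
    if nh < 1e-12:
        raise ValueError("magnetic field parallel to gravity: heading undefined")
    north_s = mh / nh
    east_s = np.cross(north_s, up_s)
    # columns of R_S_E are the E axes in the sensor frame
    r_s_e = np.column_stack([east_s, north_s, up_s])
    return matrix_to_quat(r_s_e.T)


def _sigma_weights(n: int, p: UkfParams) -> tuple[float, np.ndarray, np.ndarray]:
    lam = p.alpha**2 * (n + p.kappa) - n
    wm = np.full(2 * n + 1, 1.0 / (2 * (n + lam)))
    wc = wm.copy()
    wm[0] = lam / (n + lam)
    wc[0] = lam / (n + lam) + (1 - p.alpha**2 + p.beta)
    return n + lam, wm, wc


def estimate_orientation(
    t: np.ndarray,
    gyro: np.ndarray,
    acc: np.ndarray,
    mag: np.ndarray,
    params: UkfParams | None = None,
    initial_q: Optional[np.ndarray] = None,
    frame_from: str = "S",
) -> RotationSeries:
    """Run the attitude UKF over one IMU stream.

    Parameters are per-sample arrays: ``t (n,)`` strictly increasing,
    ``gyro/acc/mag (n, 3)``.  ``initial_q`` defaults to the analytic
    accelerometer/magnetometer solution at the first sample.  Returns the
    per-sample orientation of the sensor frame w.r.t. *E* with attitude
    covariance.
    """
    p = params or UkfParams()
    t = np.asarray(t, dtype=float)
    gyro = np.asarray(gyro, dtype=float)
    acc = np.asarray(acc, dtype=float)
    mag = np.asarray(mag, dtype=float)
    n = len(t)
    if n == 0:
        raise ValueError("empty stream")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")

    if initial_q is None:
        q = triad(acc[0], mag[0])
    else:
        q = quat_normalize(np.asarray(initial_q, dtype=float))

    # Earth-frame reference directions; the magnetic dip (angle between
    # the field and the horizontal) is self-calibrated from the leading
    # quasi-static samples to average out sensor noise.
    n_cal = min(100, n)
    a_cal = acc[:n_cal]
    m_cal = mag[:n_cal]
    na_cal = np.linalg.norm(a_cal, axis=1)
    nm_cal = np.linalg.norm(m_cal, axis=1)
    ok = (na_cal > 1e-6) & (nm_cal > 1e-6)
    if not np.any(ok):
        raise ValueError("no usable samples for magnetic-dip calibration")
    dots = np.einsum("ij,ij->i", a_cal[ok] / na_cal[ok, None], m_cal[ok] / nm_cal[ok, None])
    mz = float(np.clip(dots.mean(), -1.0, 1.0))
    mh = np.sqrt(max(1.0 - mz * mz, 0.0))
    mag_ref = np.array([0.0, mh, mz])
    up_ref = np.array([0.0, 0.0, 1.0])

    dim = 6
    scale, wm, wc = _sigma_weights(dim, p)
    P = np.diag([p.p0_attitude] * 3 + [p.p0_bias] * 3)
    bias = np.zeros(3)
    r_acc_dir = (p.acc_noise_std / GRAVITY) ** 2
    r_mag = p.mag_noise_std**2

    qs = np.empty((n, 4))
    covs = np.empty((n, 3, 3))
    watchdog_run = 0
    prev_t = t[0]
    for k in range(n):
        dt = t[k] - prev_t
        prev_t = t[k]
        if dt > 0:
            # ---- predict -------------------------------------------------
            S = np.linalg.cholesky(scale * P)
            dx = np.concatenate([np.zeros((1, dim)), S.T, -S.T], axis=0)  # (13, 6)
            dq = quat_from_rotvec(dx[:, :3])
            q_sig = quat_multiply(q[None, :], dq)
            b_sig = bias[None, :] + dx[:, 3:]
            omega = gyro[k - 1][None, :] - b_sig
            q_sig = quat_multiply(q_sig, quat_from_rotvec(omega * dt))
            q_ref = quat_canonical(quat_normalize(q_sig[0]))
            e = quat_to_rotvec(quat_multiply(quat_conj(q_ref)[None, :], q_sig))
            xi = np.concatenate([e, b_sig], axis=1)
            xi_mean = wm @ xi
            d = xi - xi_mean
            P = (wc[:, None] * d).T @ d
            P[:3, :3] += (p.gyro_noise_std * dt) ** 2 * np.eye(3)
            P[3:, 3:] += p.gyro_bias_walk_std**2 * np.eye(3)
            q = quat_canonical(
                quat_normalize(quat_multiply(q_ref, quat_from_rotvec(xi_mean[:3])))
            )
            bias = xi_mean[3:]
            P = 0.5 * (P + P.T)

        # ---- update ------------------------------------------------------
        na = np.linalg.norm(acc[k])
        nm = np.linalg.norm(mag[k])
        use_acc = na > 1e-6
        use_mag = nm > 1e-6
        if use_acc or use_mag:
            S = np.linalg.cholesky(scale * P)
            dx = np.concatenate([np.zeros((1, dim)), S.T, -S.T], axis=0)
            dq = quat_from_rotvec(dx[:, :3])
            q_sig = quat_multiply(q[None, :], dq)
            q_inv = quat_conj(q_sig)
            zs = []
            z = []
            rdiag = []
            if use_acc:
                guard = 1.0
                if abs(na - GRAVITY) > p.dynamic_guard_ms2:
                    guard = p.dynamic_guard_inflation
                zs.append(quat_rotate(q_inv, up_ref))
                z.append(acc[k] / na)
                rdiag += [r_acc_dir * guard] * 3
            if use_mag:
                zs.append(quat_rotate(q_inv, mag_ref))
                z.append(mag[k] / nm)
                rdiag += [r_mag] * 3
            Z = np.concatenate(zs, axis=1)  # (13, m)
            zobs = np.concatenate(z)
            z_pred = wm @ Z
            dZ = Z - z_pred
            Pzz = (wc[:, None] * dZ).T @ dZ + np.diag(rdiag)
            Pxz = (wc[:, None] * dx).T @ dZ
            K = np.linalg.solve(Pzz.T, Pxz.T).T
            nu = zobs - z_pred
            upd = K @ nu
            if t[k] - t[0] < p.bias_freeze_time:
                upd[3:] = 0.0  # settling window: keep the bias frozen
            q = quat_canonical(quat_normalize(quat_multiply(q, quat_from_rotvec(upd[:3]))))
            bias = bias + upd[3:]
            P = P - K @ Pzz @ K.T
            P = 0.5 * (P + P.T)
            # acquisition watchdog (see UkfParams): re-acquire from the
            # analytic fix after a sustained quasi-static disagreement
            if (
                k % p.watchdog_stride == 0
                and use_acc
                and use_mag
                and abs(na - GRAVITY) <= p.dynamic_guard_ms2
            ):
                try:
                    q_fix = triad(acc[k], mag[k])
                except ValueError:
                    q_fix = None
                if q_fix is not None:
                    miss = np.linalg.norm(
                        quat_to_rotvec(quat_multiply(quat_conj(q_fix), q))
                    )
                    if miss > p.watchdog_angle:
                        watchdog_run += 1
                    else:
                        watchdog_run = max(watchdog_run - 1, 0)
                    if watchdog_run >= p.watchdog_steps:
                        q = q_fix
                        P[:3, :3] = p.p0_attitude * np.eye(3)
                        watchdog_run = 0

        qs[k] = q
        covs[k] = P[:3, :3]

    return RotationSeries(t, qs, frame_from=frame_from, frame_to="E", att_cov=covs)


def to_reference(est: RotationSeries, ref: RotationSeries, tol: float = 0.010) -> RotationSeries:
    """Express an E-frame orientation series in the mat reference frame.

    ``R_REF_S = R_REF_E · R_E_S`` with nearest-sample pairing of the two
    streams (within ``tol`` seconds).
    """
    if est.frame_to != "E" or ref.frame_to != "E":
        raise ValueError("both series must be expressed in E")
    idx = ref.nearest_indices(est.t, tol)
    q = quat_multiply(quat_conj(ref.q[idx]), est.q)
    return RotationSeries(est.t, q, frame_from=est.frame_from, frame_to="REF", att_cov=est.att_cov)


def _projected_trunk_yaw(q: np.ndarray) -> float:
    """Angle of the trunk caudal→cranial axis projected on the mat plane,
    measured from the mat long axis (y), positive toward +x."""
    yax = quat_rotate(q, np.array([0.0, 1.0, 0.0]))
    return float(np.arctan2(yax[0], yax[1]))


def _wrap_half_pi(a: float) -> float:
    """Wrap an axis-angle difference to (-pi/2, pi/2] (axes are undirected)."""
    a = (a + np.pi / 2) % np.pi - np.pi / 2
    return np.pi / 2 if a == -np.pi / 2 else a


class TrunkOrientationFuser:
    """Correct trunk-IMU yaw against the pressure-imprint orientation.

    When the imprint trust is at least ``trust_min`` the yaw about the mat
    normal is rotated so the projected trunk axis matches the imprint
    angle, and the applied offset is remembered; with low trust the last
    reliable offset is held.  Roll and pitch are never modified.
    """

    def __init__(self, trust_min: float = 0.5):
        self.trust_min = trust_min
        self.offset: Optional[float] = None

    def fuse(self, q_trunk: np.ndarray, imprint_angle: float, trust: float) -> np.ndarray:
        """One-sample fusion; ``q_trunk`` is the REF←T quaternion."""
        if trust >= self.trust_min and np.isfinite(imprint_angle):
            yaw = _projected_trunk_yaw(q_trunk)
            self.offset = _wrap_half_pi(imprint_angle - yaw)
        if self.offset is None:
            return q_trunk  # uncorrected pass-through
        # rotating about +z moves the projected axis toward -x, i.e. it
        # decreases the yaw angle as defined here: apply the negated offset
        corr = quat_from_rotvec(np.array([0.0, 0.0, -self.offset]))
        return quat_canonical(quat_normalize(quat_multiply(corr, q_trunk)))


def fuse_trunk_series(
    trunk: RotationSeries,
    imprint_t: np.ndarray,
    imprint_angle: np.ndarray,
    trust: np.ndarray,
    trust_min: float = 0.5,
) -> RotationSeries:
    """Fuse a 100 Hz trunk series with 30 Hz imprint angles (zero-order
    hold of the yaw offset between pressure frames)."""
    if trunk.frame_to != "REF":
        raise ValueError("trunk series must be expressed in REF")
    imprint_t = np.asarray(imprint_t, dtype=float)
    fuser = TrunkOrientationFuser(trust_min)
    out = np.empty_like(trunk.q)
    j = 0
    for k in range(len(trunk)):
        while j < len(imprint_t) and imprint_t[j] <= trunk.t[k]:
            # advance the offset memory through every elapsed pressure frame
            if trust[j] >= trust_min and np.isfinite(imprint_angle[j]):
                idx = k
                fuser.fuse(trunk.q[idx], imprint_angle[j], trust[j])
            j += 1
        if fuser.offset is None:
            out[k] = trunk.q[k]
        else:
            corr = quat_from_rotvec(np.array([0.0, 0.0, -fuser.offset]))
            out[k] = quat_multiply(corr, trunk.q[k])
    return RotationSeries(
        trunk.t, quat_normalize(out), frame_from=trunk.frame_from, frame_to="REF",
        att_cov=trunk.att_cov,
    )


def dynamic_acceleration(acc: np.ndarray, est: RotationSeries) -> np.ndarray:
    """Gravity-free linear acceleration in the reference frame.

    ``a_dyn = R_REF_S · a − g``; for a stationary sensor this vanishes, in
    free fall it equals −g.
    """
    acc = np.asarray(acc, dtype=float)
    single = acc.ndim == 1
    a = np.atleast_2d(acc)
    q = est.q if est.q.ndim == 2 else est.q[None, :]
    if len(q) == 1 and len(a) > 1:
        q = np.broadcast_to(q, (len(a), 4))
    out = quat_rotate(q, a) - G_VEC
    return out[0] if single else out
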
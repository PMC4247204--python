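"""Motor-pattern parameters of spontaneous infant arm movement.

Implements the full parameter suite computed from the hand trajectory and
angular-velocity data: gyro-based hand velocity, acceleration/jerk
statistics, the spectral arc length (SAL) smoothness metric, workspace
surface area and volume normalized to the frontal hemisphere, reachable
concave/convex volume, travelled path P and average speed S, plus the
validation statistics (Pearson R, Euclidean RMSE).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .geometry import (
    alpha_shape_area_2d,
    alpha_shape_volume_3d,
    convex_hull_volume,
    default_alpha,
    fit_sphere_radius,
    lambert_equal_area,
)
from .kinematics import ArmModel, Placement

__all__ = [
    "Trajectory",
    "MovementInterval",
    "MetricsReport",
    "hand_velocity_gyro",
    "hand_velocity_forearm_only",
    "lowpass",
    "hand_velocity_accel",
    "derivatives_from_position",
    "jerk_metrics",
    "segment_movements",
    "sal",
    "fit_sphere_radius",
    "workspace_area",
    "workspace_volume",
    "reachable_volume",
    "travelled_path",
    "average_speed",
    "pearson_r",
    "rmse_euclidean",
]


def _envelope_alpha(points: np.ndarray, floor_frac: float = 0.15) -> float:
    """Alpha radius for envelope estimation of trajectory data.

    The sampling-density rule (2× median nearest-neighbour spacing) is
    floored at a fraction of the cloud diameter: a trajectory samples the
    workspace along 1-D arcs, so the envelope must be connected at the
    movement scale, not the (much finer) sample-spacing scale.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    diam = float(np.linalg.norm(pts.max(axis=0) - pts.min(axis=0)))
    return max(default_alpha(pts), floor_frac * diam)


@dataclass
class Trajectory:
    """Uniformly sampled 3-D position series (metres, seconds)."""

    t: np.ndarray
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.atleast_2d(np.asarray(self.xyz, dtype=float))
        if self.xyz.shape != (len(self.t), 3):
            raise ValueError("xyz must be (n, 3) matching t")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def fs(self) -> float:
        dt = np.diff(self.t)
        if len(dt) == 0:
            raise ValueError("need at least 2 samples")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError("non-uniform sampling")
        return 1.0 / dt[0]


@dataclass
class MovementInterval:
    start: float
    end: float
    i0: int
    i1: int  # exclusive

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("interval end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class MetricsReport:
    """Per-session motor-pattern parameter record."""

    placement: str = Placement.TWO_IMUS.value
    rms_acc: Optional[float] = None  # m/s^2
    rms_jerk: Optional[float] = None  # m/s^3
    norm_mean_abs_jerk: Optional[float] = None  # m/s^3
    sal_mean: Optional[float] = None
    sal_sd: Optional[float] = None
    norm_ws_area: Optional[float] = None  # % of frontal hemisphere area
    norm_ws_volume: Optional[float] = None  # % of frontal hemisphere volume
    reach_concave: Optional[float] = None  # m^3
    reach_convex: Optional[float] = None  # m^3
    travelled_path: Optional[float] = None  # m (P)
    average_speed: Optional[float] = None  # m/s (S)
    n_movement_intervals: int = 0
    insufficient_data: bool = False

    UNITS = {
        "rms_acc": "m/s^2",
        "rms_jerk": "m/s^3",
        "norm_mean_abs_jerk": "m/s^3",
        "sal_mean": "-",
        "sal_sd": "-",
        "norm_ws_area": "%",
        "norm_ws_volume": "%",
        "reach_concave": "m^3",
        "reach_convex": "m^3",
        "travelled_path": "m",
        "average_speed": "m/s",
    }

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MetricsReport":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


# ---------------------------------------------------------------------------
# Hand velocity


def hand_velocity_gyro(
    w_ua: np.ndarray, w_fa: np.ndarray, r_ua: np.ndarray, r_fa: np.ndarray
) -> np.ndarray:
    """Hand velocity from segment angular velocities (common frame)::

        v_H = w_UA × (r_UA + r_FA) + (w_FA − w_UA) × r_FA

    ``r_UA`` is the shoulder→elbow vector, ``r_FA`` the elbow→hand vector.
    All arguments broadcast over a leading sample axis.
    """
    w_ua = np.asarray(w_ua, dtype=float)
    w_fa = np.asarray(w_fa, dtype=float)
    r_ua = np.asarray(r_ua, dtype=float)
    r_fa = np.asarray(r_fa, dtype=float)
    return np.cross(w_ua, r_ua + r_fa) + np.cross(w_fa - w_ua, r_fa)


def hand_velocity_forearm_only(w_fa: np.ndarray, r_fa_full: np.ndarray) -> np.ndarray:
    """Single-forearm-IMU hand velocity: v_H = w_FA × r (locked elbow,
    ``r`` the full shoulder→hand vector along the forearm axis)."""
    return np.cross(np.asarray(w_fa, dtype=float), np.asarray(r_fa_full, dtype=float))


# ---------------------------------------------------------------------------
# Filtering and derivatives


def lowpass(x: np.ndarray, fs: float, fc: float = 6.0, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward), DC gain 1."""
    x = np.asarray(x, dtype=float)
    if fs <= 2 * fc:
        raise ValueError("sampling rate must exceed twice the cutoff")
    n = x.shape[0]
    if n < 12 * order:
        raise ValueError("series too short to filter")
    sos = signal.butter(order, fc, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=0)


def hand_velocity_accel(
    a_dyn: np.ndarray, fs: float, band: tuple[float, float] = (0.2, 6.0)
) -> np.ndarray:
    """Hand velocity by band-passed integration of dynamic acceleration.

    The band-pass removes accelerometer bias before trapezoidal
    integration; a matching high-pass after integration removes the
    residual drift, so the velocity is zero-mean by construction.
    """
    a = np.asarray(a_dyn, dtype=float)
    sos_bp = signal.butter(2, band, btype="band", fs=fs, output="sos")
    a_f = signal.sosfiltfilt(sos_bp, a, axis=0)
    dt = 1.0 / fs
    v = np.concatenate(
        [np.zeros((1,) + a.shape[1:]), np.cumsum(0.5 * (a_f[1:] + a_f[:-1]) * dt, axis=0)],
        axis=0,
    )
    sos_hp = signal.butter(2, band[0], btype="high", fs=fs, output="sos")
    return signal.sosfiltfilt(sos_hp, v, axis=0)


def derivatives_from_position(traj: Trajectory, fc: float = 6.0) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Velocity, acceleration, jerk from position by repeated central
    differencing, low-passing each stage at ``fc`` before the next."""
    if len(traj) < 4:
        raise ValueError("need at least 4 samples")
    fs = traj.fs
    pos = lowpass(traj.xyz, fs, fc)
    vel = np.gradient(pos, traj.t, axis=0)
    acc = np.gradient(lowpass(vel, fs, fc), traj.t, axis=0)
    jerk = np.gradient(lowpass(acc, fs, fc), traj.t, axis=0)
    return vel, acc, jerk


# ---------------------------------------------------------------------------
# Jerk / smoothness


def jerk_metrics(
    t: np.ndarray, acc: np.ndarray, intervals: Sequence[MovementInterval]
) -> tuple[float, float, float]:
    """RMS acceleration, RMS jerk and normalized mean absolute jerk over
    movement intervals.

    Jerk is the first derivative of acceleration.  The normalized mean
    absolute jerk is each interval's mean |jerk| divided by the interval
    duration, averaged over intervals.
    """
    if len(intervals) == 0:
        raise ValueError("no movement intervals")
    t = np.asarray(t, dtype=float)
    acc = np.atleast_2d(np.asarray(acc, dtype=float))
    jerk = np.gradient(acc, t, axis=0)
    a_mag = np.linalg.norm(acc, axis=1)
    j_mag = np.linalg.norm(jerk, axis=1)
    sel = np.zeros(len(t), dtype=bool)
    nmaj = []
    for iv in intervals:
        sel[iv.i0 : iv.i1] = True
        nmaj.append(j_mag[iv.i0 : iv.i1].mean() / iv.duration)
    rms_acc = float(np.sqrt(np.mean(a_mag[sel] ** 2)))
    rms_jerk = float(np.sqrt(np.mean(j_mag[sel] ** 2)))
    return rms_acc, rms_jerk, float(np.mean(nmaj))


def segment_movements(
    t: np.ndarray,
    speed: np.ndarray,
    v_on: float = 0.05,
    v_off: float = 0.02,
    d_min: float = 0.3,
) -> list[MovementInterval]:
    """Hysteresis segmentation of a filtered speed trace.

    Maximal runs with speed ≥ ``v_on`` are extended outward to the
    flanking ``v_off`` crossings, merged when they overlap, and kept if at
    least ``d_min`` seconds long.
    """
    t = np.asarray(t, dtype=float)
    speed = np.asarray(speed, dtype=float)
    above = speed >= v_on
    if not np.any(above):
        return []
    idx = np.flatnonzero(above)
    # contiguous runs of the boolean mask
    splits = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[splits + 1]]) if len(idx) else []
    run_ends = np.concatenate([idx[splits], [idx[-1]]]) if len(idx) else []
    low = speed < v_off
    intervals: list[tuple[int, int]] = []
    for s, e in zip(run_starts, run_ends):
        i0 = s
        while i0 > 0 and not low[i0 - 1]:
            i0 -= 1
        i1 = e
        while i1 < len(t) - 1 and not low[i1 + 1]:
            i1 += 1
        intervals.append((int(i0), int(i1)))
    # merge overlapping / touching
    merged: list[list[int]] = []
    for i0, i1 in intervals:
        if merged and i0 <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], i1)
        else:
            merged.append([i0, i1])
    out = []
    for i0, i1 in merged:
        if t[i1] - t[i0] >= d_min:
            out.append(MovementInterval(float(t[i0]), float(t[i1]), i0, i1 + 1))
    return out


def sal(
    v_h: np.ndarray,
    fs: float,
    w_c: float = 10.0,
    df: float = 0.01,
) -> float:
    """Spectral arc length of the speed profile (dimensionless, ≤ 0).

    With ``V(w)`` the Fourier magnitude spectrum of the speed ``|v_H|``
    and ``V̂ = V / V(0)``::

        SAL = − ∫₀^{w_c} √( (1/w_c)² + (dV̂/dw)² ) dw

    evaluated on a spectrum zero-padded to ``df`` resolution.  More
    negative values indicate a less smooth (more fragmented) movement.
    The metric is invariant to velocity amplitude scaling.
    """
    v = np.asarray(v_h, dtype=float)
    speed = np.linalg.norm(v, axis=1) if v.ndim == 2 else np.abs(v)
    if len(speed) < max(4, int(0.25 * fs)):
        raise ValueError("interval too short for SAL")
    nfft = max(int(round(fs / df)), len(speed))
    spec = np.abs(np.fft.rfft(speed, n=nfft))
    if spec[0] <= 0:
        raise ValueError("degenerate movement: zero mean speed")
    vhat = spec / spec[0]
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    sel = freqs <= w_c
    vhat = vhat[sel]
    freqs = freqs[sel]
    dw = np.diff(freqs)
    dv = np.diff(vhat)
    return float(-np.sum(np.sqrt((dw / w_c) ** 2 + dv**2)))


# ---------------------------------------------------------------------------
# Workspace


def workspace_area(
    hand: np.ndarray,
    model: ArmModel,
    placement: Placement,
    alpha: Optional[float] = None,
) -> tuple[float, dict]:
    """Normalized workspace surface envelope area (% of the frontal
    hemisphere 2πr²).

    Trunk-frame hand points are projected onto the optimum workspace
    sphere (least-squares radius for TWO_IMUS; the fixed radius
    ``l_UA + l_FA`` for single-IMU placements, whose hand-shoulder
    distance is constant), their directions are mapped through the
    equal-area projection about the ventral (+z) pole, and the concave
    envelope area is measured with the alpha-shape method.  Returns
    ``(percent, patch)`` where ``patch`` carries the envelope triangles
    and fitted radius for mesh export.
    """
    pts = np.atleast_2d(np.asarray(hand, dtype=float))
    if len(pts) < 10:
        raise ValueError("need at least 10 samples")
    if placement == Placement.TWO_IMUS:
        r = fit_sphere_radius(pts)
    else:
        r = model.l_ua + model.l_fa
    norms = np.linalg.norm(pts, axis=1)
    ok = norms > 1e-9
    dirs = pts[ok] / norms[ok, None]
    plane = lambert_equal_area(dirs, pole=np.array([0.0, 0.0, 1.0]))
    if alpha is None:
        alpha = _envelope_alpha(plane)
    area_sr, tris = alpha_shape_area_2d(plane, alpha)
    pct = 100.0 * area_sr / (2.0 * np.pi)
    patch = {"radius": r, "directions": dirs, "triangles": tris}
    return float(pct), patch


def workspace_volume(hand: np.ndarray, r: float) -> float:
    """Convex-hull workspace volume as % of the frontal hemisphere ⅔πr³."""
    vol = convex_hull_volume(hand)
    return float(100.0 * vol / (2.0 / 3.0 * np.pi * r**3))


def reachable_volume(hand: np.ndarray, alpha: Optional[float] = None) -> tuple[float, float]:
    """Reachable workspace in the mat frame: (concave, convex) volume, m³.

    Concave via the alpha-shape method, convex via the quickhull convex
    hull; the alpha complex is a subset of the hull, so concave ≤ convex.
    """
    pts = np.atleast_2d(np.asarray(hand, dtype=float))
    if alpha is None:
        alpha = _envelope_alpha(pts)
    concave, _ = alpha_shape_volume_3d(pts, alpha)
    convex = convex_hull_volume(pts)
    return float(concave), float(convex)


# ---------------------------------------------------------------------------
# Path, speed, validation statistics


def travelled_path(traj: Trajectory | np.ndarray) -> float:
    """Travelled path P = Σ ‖Δxyz‖ (metres)."""
    xyz = traj.xyz if isinstance(traj, Trajectory) else np.atleast_2d(np.asarray(traj, dtype=float))
    if len(xyz) < 2:
        raise ValueError("need at least 2 samples")
    return float(np.linalg.norm(np.diff(xyz, axis=0), axis=1).sum())


def average_speed(path: float, duration: float) -> float:
    """Average speed S: travelled path normalized by session duration."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return float(path / duration)


def pearson_r(a: np.ndarray, b: np.ndarray) -> float:
    """Product-moment correlation of two equally long scalar series."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) != len(b) or len(a) < 3:
        raise ValueError("series must have equal length >= 3")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da**2).sum() * (db**2).sum())
    if denom == 0:
        raise ValueError("zero variance")
    return float((da * db).sum() / denom)


def rmse_euclidean(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square Euclidean distance between paired 3-D series."""
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("series shapes differ")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
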
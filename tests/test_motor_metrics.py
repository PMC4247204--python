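import numpy as np
import pytest

from matmotion import motor_metrics as mm
from matmotion.kinematics import ArmModel, Placement


# ---------------------------------------------------------------------------
# Hand velocity


def test_hand_velocity_gyro_cases(rng):
    r_ua = np.array([0.0, 0.07, 0.0])
    r_fa = np.array([0.0, 0.07, 0.0])
    assert np.allclose(mm.hand_velocity_gyro(np.zeros(3), np.zeros(3), r_ua, r_fa), 0.0)
    # rigid whole arm: the formula collapses to w x (r_ua + r_fa)
    w = rng.normal(size=(20, 3))
    v = mm.hand_velocity_gyro(w, w, r_ua, r_fa)
    assert np.allclose(v, np.cross(w, r_ua + r_fa), atol=1e-15)
    # locked elbow equals the forearm-only formula
    v2 = mm.hand_velocity_forearm_only(w, r_ua + r_fa)
    assert np.allclose(v, v2, atol=1e-15)


def test_hand_velocity_forearm_only_degeneracies(rng):
    r = np.array([0.0, 0.14, 0.0])
    assert np.allclose(mm.hand_velocity_forearm_only(np.zeros(3), r), 0.0)
    # pure axial spin moves nothing
    assert np.allclose(mm.hand_velocity_forearm_only(np.array([0.0, 3.0, 0.0]), r), 0.0)


def test_hand_velocity_gyro_matches_differentiation_oracle():
    """Angular-velocity chain vs numerical differentiation of the true
    hand position on a noise-free simulated reach."""
    from matmotion.quaternions import quat_rotate
    from matmotion.simulator import DollModel, Reach, arm_trajectory, _body_rates

    doll = DollModel()
    reach = Reach("right", (0.1, -0.3, 0.9), 0.09, 0.8)
    start = np.array([-0.02, 0.06, 0.10])
    p, q_ua, q_fa = arm_trajectory(reach, doll, start)
    fs = 100.0
    w_ua_body = _body_rates(q_ua, fs)
    w_fa_body = _body_rates(q_fa, fs)
    w_ua = quat_rotate(q_ua, w_ua_body)
    w_fa = quat_rotate(q_fa, w_fa_body)
    p_el = quat_rotate(q_ua, np.array([0.0, doll.l_ua, 0.0]))
    # body rates are forward increments (valid at t + dt/2): evaluate the
    # chain with mid-sample lever arms against the forward difference
    r_ua_mid = 0.5 * (p_el[:-1] + p_el[1:])
    r_fa_mid = 0.5 * ((p - p_el)[:-1] + (p - p_el)[1:])
    v = mm.hand_velocity_gyro(w_ua[:-1], w_fa[:-1], r_ua_mid, r_fa_mid)
    v_ref = np.diff(p, axis=0) * fs
    peak = np.max(np.linalg.norm(v_ref, axis=1))
    rms = np.sqrt(np.mean(np.sum((v - v_ref) ** 2, axis=1)))
    assert rms < 0.01 * peak


# ---------------------------------------------------------------------------
# Filtering


def test_lowpass_frequency_response():
    fs = 100.0
    t = np.arange(0, 10, 1 / fs)
    assert np.allclose(mm.lowpass(np.full_like(t, 3.3), fs), 3.3, atol=1e-9)
    s1 = np.sin(2 * np.pi * 1.0 * t)
    out1 = mm.lowpass(s1, fs)
    assert np.max(np.abs(out1[200:-200])) > 0.99  # 1 Hz passes
    s20 = np.sin(2 * np.pi * 20.0 * t)
    out20 = mm.lowpass(s20, fs)
    assert np.max(np.abs(out20[200:-200])) < 0.10  # 20 Hz attenuated > 90 %
    with pytest.raises(ValueError):
        mm.lowpass(np.ones(5), fs)


def test_hand_velocity_accel_sinusoid_and_drift():
    fs = 100.0
    t = np.arange(0, 60, 1 / fs)
    A, f0 = 2.0, 2.0
    a = np.column_stack([A * np.sin(2 * np.pi * f0 * t), np.zeros_like(t), np.zeros_like(t)])
    assert np.allclose(mm.hand_velocity_accel(np.zeros_like(a), fs), 0.0, atol=1e-12)
    v = mm.hand_velocity_accel(a, fs)
    expect = A / (2 * np.pi * f0)
    # interior window clear of the slow high-pass transients
    mid = slice(2000, -2000)
    assert np.max(np.abs(v[mid, 0])) == pytest.approx(expect, rel=0.05)
    assert abs(np.mean(v[mid, 0])) < 0.02 * expect
    # constant bias: naive integration drifts linearly, band-pass kills it
    bias = np.full_like(a, 0.1)
    v_b = mm.hand_velocity_accel(bias, fs)
    naive_terminal = 0.1 * t[-1]
    assert np.sqrt(np.mean(v_b**2)) < 0.01 * naive_terminal


def test_derivatives_from_position_polynomials_and_sinusoid():
    fs = 100.0
    t = np.arange(0, 6, 1 / fs)
    ramp = np.column_stack([0.2 * t, -0.1 * t, 0.05 * t])
    vel, acc, _ = mm.derivatives_from_position(mm.Trajectory(t, ramp))
    mid = slice(150, -150)
    assert np.allclose(vel[mid], [0.2, -0.1, 0.05], atol=1e-6)
    assert np.allclose(acc[mid], 0.0, atol=1e-4)
    quad = np.column_stack([0.5 * t**2, np.zeros_like(t), np.zeros_like(t)])
    _, acc_q, _ = mm.derivatives_from_position(mm.Trajectory(t, quad))
    assert np.allclose(acc_q[mid, 0], 1.0, atol=1e-3)
    f0 = 0.8
    sine = np.column_stack([np.sin(2 * np.pi * f0 * t), np.zeros_like(t), np.zeros_like(t)])
    _, _, jerk = mm.derivatives_from_position(mm.Trajectory(t, sine))
    jerk_true = -((2 * np.pi * f0) ** 3) * np.cos(2 * np.pi * f0 * t)
    rms = np.sqrt(np.mean((jerk[mid, 0] - jerk_true[mid]) ** 2))
    assert rms < 0.03 * np.max(np.abs(jerk_true))
    with pytest.raises(ValueError):
        mm.derivatives_from_position(mm.Trajectory(t[:3], ramp[:3]))
    with pytest.raises(ValueError):
        mm.Trajectory(np.array([0, 0.01, 0.5, 0.51]), ramp[:4]).fs


# ---------------------------------------------------------------------------
# Jerk metrics & segmentation


def minimum_jerk_profiles(d=0.1, T=1.0, fs=100.0):
    t = np.arange(0, T + 1 / fs, 1 / fs)
    tau = t / T
    v = 30 * d / T * (tau**2 - 2 * tau**3 + tau**4)
    a = 30 * d / T**2 * (2 * tau - 6 * tau**2 + 4 * tau**3)
    j = 30 * d / T**3 * (2 - 12 * tau + 12 * tau**2)
    return t, v, a, j


def test_jerk_metrics_cases():
    t = np.arange(0, 2, 0.01)
    iv = [mm.MovementInterval(0.5, 1.5, 50, 151)]
    const = np.tile([0.0, 3.0, 4.0], (len(t), 1))  # |a| = 5 everywhere
    rms_acc, rms_jerk, _ = mm.jerk_metrics(t, const, iv)
    assert rms_acc == pytest.approx(5.0, rel=1e-9)
    assert rms_jerk == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        mm.jerk_metrics(t, const, [])


def test_jerk_metrics_minimum_jerk_analytic():
    """RMS acceleration/jerk on a minimum-jerk reach match the analytic
    profiles integrated by direct quadrature."""
    d, T, fs = 0.1, 1.0, 100.0
    t, v, a, j = minimum_jerk_profiles(d, T, fs)
    acc3 = np.column_stack([a, np.zeros_like(a), np.zeros_like(a)])
    iv = [mm.MovementInterval(t[0], t[-1], 0, len(t))]
    rms_acc, rms_jerk, nmaj = mm.jerk_metrics(t, acc3, iv)
    rms_acc_true = np.sqrt(np.trapezoid(a**2, t) / T)
    rms_jerk_true = np.sqrt(np.trapezoid(j**2, t) / T)
    mean_abs_jerk_true = np.trapezoid(np.abs(j), t) / T
    assert rms_acc == pytest.approx(rms_acc_true, rel=0.02)
    assert rms_jerk == pytest.approx(rms_jerk_true, rel=0.02)
    assert nmaj == pytest.approx(mean_abs_jerk_true / T, rel=0.02)


def test_segment_movements_cases():
    fs = 100.0
    t = np.arange(0, 10, 1 / fs)
    assert mm.segment_movements(t, np.zeros_like(t)) == []
    bell = 0.2 * np.exp(-((t - 5.0) ** 2) / (2 * 0.3**2))
    iv = mm.segment_movements(t, bell)
    assert len(iv) == 1
    assert iv[0].start < 5.0 < iv[0].end
    # hysteresis: interval extends to the v_off crossings
    assert bell[iv[0].i0] < 0.05 and bell[iv[0].i1 - 1] < 0.05


def test_segment_movements_counts_simulated_reaches():
    """A roll-free script with k well-separated reaches yields exactly k
    intervals on the true hand speed."""
    from matmotion.simulator import (
        DollModel,
        MotionScript,
        NoiseParams,
        Reach,
        Rest,
        simulate_session,
    )

    prims = [Rest(1.0)]
    dirs = [(0.3, -0.2, 0.9), (-0.3, -0.2, 0.9), (0.5, 0.1, 0.8)]
    for d in dirs:
        prims += [Reach("right", d, 0.08, 0.7), Rest(1.0),
                  Reach("right", tuple(-x for x in d), 0.08, 0.7), Rest(1.0)]
    bundle, truth = simulate_session(
        DollModel(), MotionScript(prims), NoiseParams.zero(), seed=0
    )
    k_scripted = sum(1 for s, e, a in truth.intervals if a == "right")
    v = np.gradient(truth.p_hand["right"], truth.t, axis=0)
    speed = np.linalg.norm(v, axis=1)
    iv = mm.segment_movements(truth.t, speed)
    assert len(iv) == k_scripted == 6


# ---------------------------------------------------------------------------
# SAL


def sal_quadrature_oracle(v_func, T, w_c=10.0, dw=0.001, dt=1e-4):
    """Dense-quadrature SAL: continuous Fourier magnitude of the analytic
    speed profile on a fine frequency grid, then arc length by direct
    summation."""
    t = np.arange(0, T, dt)
    v = v_func(t)
    w = np.arange(0, w_c + dw, dw)
    ker = np.exp(-2j * np.pi * np.outer(w, t))
    V = np.abs(ker @ v) * dt
    vhat = V / V[0]
    return -np.sum(np.sqrt((np.diff(w) / w_c) ** 2 + np.diff(vhat) ** 2))


def test_sal_amplitude_invariance(rng):
    fs = 100.0
    t = np.arange(0, 1.0, 1 / fs)
    v = np.column_stack([0.1 * np.sin(np.pi * t) ** 2, np.zeros_like(t), np.zeros_like(t)])
    assert mm.sal(v, fs) == pytest.approx(mm.sal(7.3 * v, fs), abs=1e-12)
    assert mm.sal(v, fs) < 0


def test_sal_matches_dense_quadrature_oracle():
    d, T, fs = 0.1, 1.0, 100.0

    def v_func(t):
        tau = t / T
        return 30 * d / T * (tau**2 - 2 * tau**3 + tau**4)

    t = np.arange(0, T, 1 / fs)
    got = mm.sal(v_func(t), fs)
    expected = sal_quadrature_oracle(v_func, T)
    assert got == pytest.approx(expected, rel=0.01)


def test_sal_two_submovements_less_smooth():
    """Splitting one reach into two submovements of the same total
    duration makes SAL strictly more negative (oracle comparison)."""
    T, fs = 1.2, 100.0

    def single(t):
        tau = np.clip(t / T, 0, 1)
        return 30 * 0.1 / T * (tau**2 - 2 * tau**3 + tau**4)

    def double(t):
        half = T / 2
        tau1 = np.clip(t / half, 0, 1)
        tau2 = np.clip((t - half) / half, 0, 1)
        b = lambda tau: tau**2 - 2 * tau**3 + tau**4
        return 30 * 0.05 / half * (b(tau1) + b(tau2))

    t = np.arange(0, T, 1 / fs)
    sal1 = mm.sal(single(t), fs)
    sal2 = mm.sal(double(t), fs)
    assert sal2 < sal1
    assert sal_quadrature_oracle(double, T) < sal_quadrature_oracle(single, T)


def test_sal_degenerate_errors():
    with pytest.raises(ValueError):
        mm.sal(np.zeros((100, 3)), 100.0)
    with pytest.raises(ValueError):
        mm.sal(np.ones((5, 3)), 100.0)


# ---------------------------------------------------------------------------
# Sphere fit and workspace


def test_fit_sphere_radius_cases(rng):
    dirs = rng.normal(size=(1000, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    assert mm.fit_sphere_radius(0.14 * dirs) == pytest.approx(0.14, abs=1e-12)
    radii = np.where(np.arange(1000) % 2 == 0, 0.13, 0.15)
    assert mm.fit_sphere_radius(radii[:, None] * dirs) == pytest.approx(0.14, abs=1e-12)
    noisy = (0.14 + rng.normal(0, 0.001, 1000))[:, None] * dirs
    assert abs(mm.fit_sphere_radius(noisy) - 0.14) < 0.0005
    with pytest.raises(ValueError):
        mm.fit_sphere_radius(np.zeros((3, 3)))


def fibonacci_hemisphere(n, r=1.0):
    i = np.arange(n)
    z = (i + 0.5) / n  # upper hemisphere only
    phi = np.pi * (1 + 5**0.5) * i
    s = np.sqrt(1 - z**2)
    return r * np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def test_workspace_area_dense_hemisphere():
    pts = fibonacci_hemisphere(3000, r=0.13)
    model = ArmModel("right", 0.065, 0.065)
    pct, patch = mm.workspace_area(pts, model, Placement.TWO_IMUS)
    assert pct == pytest.approx(100.0, abs=5.0)
    assert patch["radius"] == pytest.approx(0.13, abs=1e-9)


def test_workspace_area_spherical_cap_closed_form(rng):
    half_angle = np.deg2rad(10.0)
    n = 2000
    # dense sampling of a polar cap
    z = rng.uniform(np.cos(half_angle), 1.0, n)
    phi = rng.uniform(0, 2 * np.pi, n)
    s = np.sqrt(1 - z**2)
    pts = 0.14 * np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    pct, _ = mm.workspace_area(pts, ArmModel("right"), Placement.FOREARM_ONLY)
    expected = (1 - np.cos(half_angle)) * 100.0
    assert pct == pytest.approx(expected, rel=0.2)


def test_workspace_area_scale_invariance():
    pts = fibonacci_hemisphere(800, r=0.1)
    pct1, _ = mm.workspace_area(pts, ArmModel("right"), Placement.TWO_IMUS)
    pct2, _ = mm.workspace_area(2 * pts, ArmModel("right"), Placement.TWO_IMUS)
    assert pct1 == pytest.approx(pct2, rel=1e-9)
    with pytest.raises(ValueError):
        mm.workspace_area(pts[:5], ArmModel("right"), Placement.TWO_IMUS)


def test_workspace_area_rotation_invariance(rng):
    from matmotion.quaternions import quat_from_rotvec, quat_rotate

    half = np.deg2rad(25.0)
    z = rng.uniform(np.cos(half), 1.0, 1500)
    phi = rng.uniform(0, 2 * np.pi, 1500)
    s = np.sqrt(1 - z**2)
    pts = 0.14 * np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    pct, _ = mm.workspace_area(pts, ArmModel("right"), Placement.TWO_IMUS)
    q = quat_from_rotvec(np.array([0.3, -0.2, 0.1]))  # keeps cloud ventral
    pct_rot, _ = mm.workspace_area(quat_rotate(q, pts), ArmModel("right"), Placement.TWO_IMUS)
    assert pct_rot == pytest.approx(pct, rel=0.1)


def test_workspace_volume_cases(rng):
    r = 0.14
    n = 6000
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    dirs[:, 2] = np.abs(dirs[:, 2])
    radii = r * rng.uniform(0, 1, n) ** (1 / 3)
    pts = radii[:, None] * dirs
    assert mm.workspace_volume(pts, r) == pytest.approx(100.0, abs=5.0)
    # known tetrahedron: hull volume equals the determinant formula
    tet = np.array([[0, 0, 0], [0.1, 0, 0], [0, 0.2, 0], [0, 0, 0.3]])
    expected_pct = (abs(np.linalg.det(tet[1:] - tet[0])) / 6) / (2 / 3 * np.pi * r**3) * 100
    assert mm.workspace_volume(tet, r) == pytest.approx(expected_pct, rel=1e-9)
    # adding interior points leaves the hull volume unchanged
    interior = np.vstack([tet, [[0.02, 0.03, 0.05]]])
    assert mm.workspace_volume(interior, r) == pytest.approx(mm.workspace_volume(tet, r), rel=1e-12)


def test_reachable_volume_cases(rng):
    cube = np.array(
        [[x, y, z] for x in (0, 0.1) for y in (0, 0.1) for z in (0, 0.1)], dtype=float
    )
    concave, convex = mm.reachable_volume(cube)
    assert convex == pytest.approx(0.001, rel=1e-9)
    for _ in range(20):
        cloud = rng.normal(size=(60, 3))
        c, v = mm.reachable_volume(cloud)
        assert c <= v + 1e-12


def test_reachable_volume_l_shaped_solid(rng):
    """Grid sampling of an L-shaped solid: the concave volume approaches
    the analytic L volume, the convex the hull (pentagonal prism)."""
    g = np.linspace(0.0, 1.0, 17)
    X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    keep = ~((pts[:, 0] > 0.5) & (pts[:, 1] > 0.5))
    pts = pts[keep]
    concave, convex = mm.reachable_volume(pts)
    assert concave == pytest.approx(0.75, rel=0.15)
    assert convex == pytest.approx(0.875, rel=0.05)


# ---------------------------------------------------------------------------
# Path, speed, statistics


def test_travelled_path_and_average_speed(rng):
    t = np.arange(0, 10, 0.01)
    still = mm.Trajectory(t, np.tile([0.1, 0.2, 0.3], (len(t), 1)))
    assert mm.travelled_path(still) == 0.0
    assert mm.average_speed(0.0, 10.0) == 0.0
    line = mm.Trajectory(t, np.column_stack([np.linspace(0, 1, len(t)), np.zeros(len(t)), np.zeros(len(t))]))
    P = mm.travelled_path(line)
    assert P == pytest.approx(1.0, abs=1e-12)
    assert mm.average_speed(P, 10.0) == pytest.approx(0.1, abs=1e-12)
    walk = rng.normal(size=(500, 3)).cumsum(axis=0)
    expected = sum(np.linalg.norm(walk[i + 1] - walk[i]) for i in range(len(walk) - 1))
    assert mm.travelled_path(walk) == pytest.approx(expected, abs=1e-9)


def test_path_additivity_and_lower_bound(rng):
    a = rng.normal(size=(100, 3)).cumsum(axis=0)
    b = a[-1] + rng.normal(size=(100, 3)).cumsum(axis=0)
    whole = np.vstack([a, b])
    split = mm.travelled_path(a) + mm.travelled_path(b) + np.linalg.norm(b[0] - a[-1])
    assert mm.travelled_path(whole) == pytest.approx(split, rel=1e-12)
    assert mm.travelled_path(whole) >= np.linalg.norm(whole[-1] - whole[0])


def test_pearson_r_cases(rng):
    a = rng.normal(size=10)
    assert mm.pearson_r(a, 2 * a + 1) == pytest.approx(1.0, abs=1e-12)
    assert mm.pearson_r(a, -a) == pytest.approx(-1.0, abs=1e-12)
    b = rng.normal(size=10)
    da, db = a - a.mean(), b - b.mean()
    expected = (da * db).sum() / np.sqrt((da**2).sum() * (db**2).sum())
    assert mm.pearson_r(a, b) == pytest.approx(expected, abs=1e-12)
    with pytest.raises(ValueError):
        mm.pearson_r(a, np.full(10, 2.0))
    with pytest.raises(ValueError):
        mm.pearson_r(a[:3], b[:4])


def test_rmse_euclidean_cases(rng):
    a = rng.normal(size=(50, 3))
    assert mm.rmse_euclidean(a, a) == 0.0
    d = np.array([0.3, -0.4, 0.0])
    assert mm.rmse_euclidean(a, a + d) == pytest.approx(0.5, abs=1e-12)
    b = rng.normal(size=(50, 3))
    expected = np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))
    assert mm.rmse_euclidean(a, b) == pytest.approx(expected, abs=1e-12)
    with pytest.raises(ValueError):
        mm.rmse_euclidean(a, b[:10])
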
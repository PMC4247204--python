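"""Unit-quaternion algebra (Hamilton convention, scalar-first).

All functions are vectorized over leading axes: a "quaternion array" has
shape ``(..., 4)`` with the scalar part first, and represents the rotation
that maps body-frame vectors into the parent frame, ``v_parent = q ⊛ v_body``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "quat_normalize",
    "quat_conj",
    "quat_multiply",
    "quat_rotate",
    "quat_from_rotvec",
    "quat_to_rotvec",
    "quat_to_matrix",
    "matrix_to_quat",
    "quat_canonical",
]


def quat_normalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def quat_conj(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    out = q.copy()
    out[..., 1:] = -out[..., 1:]
    return out


def quat_multiply(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Hamilton product p ⊗ q (composition: p then q applied in p's body frame)."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    pw, px, py, pz = p[..., 0], p[..., 1], p[..., 2], p[..., 3]
    qw, qx, qy, qz = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    return np.stack(
        [
            pw * qw - px * qx - py * qy - pz * qz,
            pw * qx + px * qw + py * qz - pz * qy,
            pw * qy - px * qz + py * qw + pz * qx,
            pw * qz + px * qy - py * qx + pz * qw,
        ],
        axis=-1,
    )


def _cross3(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Component-wise 3-vector cross product (no np.cross axis overhead)."""
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def quat_rotate(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotate vectors ``v`` (..., 3) by quaternions ``q`` (..., 4)."""
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    w = q[..., :1]
    u = q[..., 1:]
    uv = _cross3(u, v)
    return v + 2.0 * _cross3(u, uv + w * v)


def quat_from_rotvec(rv: np.ndarray) -> np.ndarray:
    """Exponential map: rotation vector (axis * angle, rad) → quaternion."""
    rv = np.asarray(rv, dtype=float)
    angle = np.linalg.norm(rv, axis=-1, keepdims=True)
    half = 0.5 * angle
    # sin(x)/x with series fallback near zero
    small = angle < 1e-9
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(small, 0.5 - angle**2 / 48.0, np.sin(half) / np.where(angle == 0, 1.0, angle))
    w = np.cos(half)
    xyz = k * rv
    return np.concatenate([w, xyz], axis=-1)


def quat_to_rotvec(q: np.ndarray) -> np.ndarray:
    """Logarithmic map: quaternion → rotation vector in (-π, π]."""
    q = quat_canonical(quat_normalize(q))
    w = np.clip(q[..., 0], -1.0, 1.0)
    xyz = q[..., 1:]
    norm = np.linalg.norm(xyz, axis=-1)
    angle = 2.0 * np.arctan2(norm, w)
    small = norm < 1e-12
    scale = np.where(small, 2.0, angle / np.where(small, 1.0, norm))
    return scale[..., None] * xyz


def quat_to_matrix(q: np.ndarray) -> np.ndarray:
    """Quaternion → 3×3 rotation matrix (maps body vectors to parent frame)."""
    q = quat_normalize(q)
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    m = np.empty(q.shape[:-1] + (3, 3), dtype=float)
    m[..., 0, 0] = 1 - 2 * (y * y + z * z)
    m[..., 0, 1] = 2 * (x * y - w * z)
    m[..., 0, 2] = 2 * (x * z + w * y)
    m[..., 1, 0] = 2 * (x * y + w * z)
    m[..., 1, 1] = 1 - 2 * (x * x + z * z)
    m[..., 1, 2] = 2 * (y * z - w * x)
    m[..., 2, 0] = 2 * (x * z - w * y)
    m[..., 2, 1] = 2 * (y * z + w * x)
    m[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return m


def matrix_to_quat(m: np.ndarray) -> np.ndarray:
    """3×3 rotation matrix → quaternion (Shepperd's method, vectorized)."""
    m = np.asarray(m, dtype=float)
    batch = m.shape[:-2]
    mm = m.reshape((-1, 3, 3))
    n = mm.shape[0]
    q = np.empty((n, 4))
    tr = np.trace(mm, axis1=-2, axis2=-1)
    diag = np.stack([mm[:, 0, 0], mm[:, 1, 1], mm[:, 2, 2]], axis=-1)
    # choose the numerically largest pivot per matrix
    choice = np.where(tr > diag.max(axis=-1), 3, diag.argmax(axis=-1))
    for c in range(4):
        idx = np.nonzero(choice == c)[0]
        if idx.size == 0:
            continue
        r = mm[idx]
        if c == 3:
            s = np.sqrt(1.0 + tr[idx]) * 2.0
            q[idx, 0] = 0.25 * s
            q[idx, 1] = (r[:, 2, 1] - r[:, 1, 2]) / s
            q[idx, 2] = (r[:, 0, 2] - r[:, 2, 0]) / s
            q[idx, 3] = (r[:, 1, 0] - r[:, 0, 1]) / s
        else:
            i, j, k = c, (c + 1) % 3, (c + 2) % 3
            s = np.sqrt(1.0 + r[:, i, i] - r[:, j, j] - r[:, k, k]) * 2.0
            q[idx, 0] = (r[:, k, j] - r[:, j, k]) / s
            q[idx, 1 + i] = 0.25 * s
            q[idx, 1 + j] = (r[:, j, i] + r[:, i, j]) / s
            q[idx, 1 + k] = (r[:, k, i] + r[:, i, k]) / s
    return quat_canonical(quat_normalize(q.reshape(batch + (4,))))


def quat_canonical(q: np.ndarray) -> np.ndarray:
    """Fix the double-cover sign so the scalar part is non-negative."""
    q = np.asarray(q, dtype=float)
    sign = np.where(q[..., :1] < 0, -1.0, 1.0)
    return q * sign
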
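"""Computational-geometry primitives for workspace estimation.

Alpha shapes are realized as alpha complexes on scipy Delaunay
triangulations: simplices whose circumradius exceeds the alpha radius are
discarded, and the retained area/volume is summed.  Spherical (workspace
envelope) areas are measured through the Lambert azimuthal equal-area
projection, which maps spherical area exactly onto planar area.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, cKDTree

__all__ = [
    "fit_sphere_radius",
    "default_alpha",
    "lambert_equal_area",
    "alpha_shape_area_2d",
    "alpha_shape_volume_3d",
    "convex_hull_volume",
]


def fit_sphere_radius(points: np.ndarray) -> float:
    """Least-squares sphere radius about a fixed centre at the origin.

    Minimizing Σ(‖p_i‖ − r)² gives r* = mean ‖p_i‖.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 4:
        raise ValueError("need at least 4 points")
    norms = np.linalg.norm(pts, axis=1)
    r = float(norms.mean())
    if r <= 0:
        raise ValueError("degenerate point set at the origin")
    return r


def default_alpha(points: np.ndarray, scale: float = 2.0) -> float:
    """Scale-adaptive alpha radius: ``scale`` × median nearest-neighbour
    spacing of the point set."""
    pts = np.unique(np.atleast_2d(np.asarray(points, dtype=float)), axis=0)
    if len(pts) < 2:
        raise ValueError("alpha undefined for fewer than 2 distinct points")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=2)
    spacing = d[:, 1]
    spacing = spacing[spacing > 0]
    if len(spacing) == 0:
        raise ValueError("coincident points: alpha undefined")
    return scale * float(np.median(spacing))


def lambert_equal_area(dirs: np.ndarray, pole: np.ndarray = np.array([0.0, 0.0, 1.0])) -> np.ndarray:
    """Lambert azimuthal equal-area projection of unit vectors about ``pole``.

    Planar area equals solid angle on the unit sphere; the hemisphere
    around the pole maps onto the disc of radius √2 (area 2π).
    """
    d = np.atleast_2d(np.asarray(dirs, dtype=float))
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    pole = np.asarray(pole, dtype=float)
    pole = pole / np.linalg.norm(pole)
    # orthonormal tangent basis at the pole
    a = np.array([1.0, 0.0, 0.0])
    if abs(pole @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(pole, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(pole, e1)
    cosz = np.clip(d @ pole, -1.0, 1.0)
    k = np.sqrt(np.maximum(2.0 / (1.0 + cosz), 0.0))
    return np.column_stack([k * (d @ e1), k * (d @ e2)])


def _tri_circumradius(p: np.ndarray) -> np.ndarray:
    """Circumradii of triangles (m, 3, 2) or (m, 3, 3)."""
    a = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    b = np.linalg.norm(p[:, 0] - p[:, 2], axis=1)
    c = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    if p.shape[2] == 2:
        u = p[:, 1] - p[:, 0]
        v = p[:, 2] - p[:, 0]
        area2 = np.abs(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])
    else:
        area2 = np.linalg.norm(np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = a * b * c / (2.0 * area2)
    r[~np.isfinite(r)] = np.inf
    return r


def alpha_shape_area_2d(points: np.ndarray, alpha: Optional[float] = None) -> tuple[float, np.ndarray]:
    """Area of the 2-D alpha complex; returns (area, kept triangle indices).

    Triangles of the Delaunay triangulation with circumradius ≤ ``alpha``
    are retained; their areas are summed (they partition the complex).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    if alpha is None:
        alpha = default_alpha(pts)
    tri = Delaunay(pts)
    corners = pts[tri.simplices]  # (m, 3, 2)
    keep = _tri_circumradius(corners) <= alpha
    v1 = corners[keep, 1] - corners[keep, 0]
    v2 = corners[keep, 2] - corners[keep, 0]
    areas = 0.5 * np.abs(v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0])
    return float(areas.sum()), tri.simplices[keep]


def _tet_circumradius(p: np.ndarray) -> np.ndarray:
    """Circumradii of tetrahedra (m, 4, 3)."""
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    A = np.stack([a, b, c], axis=1)  # (m, 3, 3)
    rhs = 0.5 * np.stack(
        [np.sum(a * a, axis=1), np.sum(b * b, axis=1), np.sum(c * c, axis=1)], axis=1
    )
    det = np.linalg.det(A)
    r = np.full(len(p), np.inf)
    ok = np.abs(det) > 1e-14
    if np.any(ok):
        centre = np.linalg.solve(A[ok], rhs[ok][..., None])[..., 0]
        r[ok] = np.linalg.norm(centre, axis=1)
    return r


def alpha_shape_volume_3d(points: np.ndarray, alpha: Optional[float] = None) -> tuple[float, np.ndarray]:
    """Volume of the 3-D alpha complex; returns (volume, kept tetrahedra)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 4:
        raise ValueError("need at least 4 points")
    if alpha is None:
        alpha = default_alpha(pts)
    tri = Delaunay(pts)
    corners = pts[tri.simplices]  # (m, 4, 3)
    keep = _tet_circumradius(corners) <= alpha
    kept = corners[keep]
    a = kept[:, 1] - kept[:, 0]
    b = kept[:, 2] - kept[:, 0]
    c = kept[:, 3] - kept[:, 0]
    vols = np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0
    return float(vols.sum()), tri.simplices[keep]


def convex_hull_volume(points: np.ndarray) -> float:
    """Convex-hull (quickhull) volume of a 3-D point set."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < 4:
        raise ValueError("need at least 4 points")
    try:
        return float(ConvexHull(pts).volume)
    except Exception as exc:  # qhull raises on coplanar input
        raise ValueError(f"degenerate point set: {exc}") from exc
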
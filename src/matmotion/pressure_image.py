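"""Pressure-mattress image processing.

The mattress delivers 30 Hz grayscale frames of 55 × 32 piezoresistive
sensor loads covering a 0.80 m × 0.47 m sensitive area.  This module turns
raw frames into the landmarks the posture pipeline needs: bias/noise
removal, 8-connected imprint labelling, Delaunay-based upsampling to
165 × 96, centre of pressure (COP), trunk-imprint orientation from central
image moments with an attached trust level, and shoulder/head detection.

Coordinate conventions
----------------------
Grid rows (index ``i``, 55 at raw resolution) run along the mat long axis
(*y*, metres), columns (index ``j``, 32) across the mat (*x*).  The pixel
centre of cell ``(i, j)`` on an ``H × W`` grid sits at
``y = (i + 0.5) * 0.80 / H``,  ``x = (j + 0.5) * 0.47 / W``; the origin is
the mat corner carrying the reference IMU.  2-D points are ``(x, y)``
metres; 3-D points add *z* upward from the mat surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from scipy.spatial import Delaunay

MAT_LENGTH_M = 0.80  # along rows / y
MAT_WIDTH_M = 0.47  # along columns / x
RAW_SHAPE = (55, 32)
UPSAMPLE_FACTOR = 3
UPSAMPLED_SHAPE = (RAW_SHAPE[0] * UPSAMPLE_FACTOR, RAW_SHAPE[1] * UPSAMPLE_FACTOR)

_EIGHT_CONN = np.ones((3, 3), dtype=int)


@dataclass
class PressureFrame:
    """One time-stamped pressure image (non-negative loads, device units)."""

    t: float
    grid: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("pressure grid must be 2-D")
        if np.any(self.grid < 0):
            raise ValueError("pressure loads must be non-negative")

    @property
    def resolution(self) -> str:
        if self.grid.shape == RAW_SHAPE:
            return "RAW"
        if self.grid.shape == UPSAMPLED_SHAPE:
            return "UPSAMPLED"
        return "OTHER"

    @property
    def pitch(self) -> tuple[float, float]:
        """(dy, dx) pixel pitch in metres."""
        h, w = self.grid.shape
        return MAT_LENGTH_M / h, MAT_WIDTH_M / w


def pixel_centers(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Return (y of rows, x of cols) pixel-centre coordinates in metres."""
    h, w = shape
    y = (np.arange(h) + 0.5) * (MAT_LENGTH_M / h)
    x = (np.arange(w) + 0.5) * (MAT_WIDTH_M / w)
    return y, x


@dataclass
class ImprintObject:
    """A maximal 8-connected region of loaded pixels with its properties."""

    pixels: np.ndarray  # (n, 2) int row/col indices
    grid_shape: tuple[int, int]
    values: np.ndarray  # (n,) loads

    @property
    def area(self) -> int:
        return len(self.pixels)

    @property
    def load(self) -> float:
        return float(self.values.sum())

    @property
    def min_load(self) -> float:
        return float(self.values.min())

    @property
    def max_load(self) -> float:
        return float(self.values.max())

    @property
    def centroid_rc(self) -> np.ndarray:
        """Load-weighted centroid in (row, col) pixel units."""
        w = self.values / self.values.sum()
        return (self.pixels * w[:, None]).sum(axis=0)

    @property
    def centroid_xy(self) -> np.ndarray:
        """Load-weighted centroid in mat metres (x, y)."""
        rc = self.centroid_rc
        dy = MAT_LENGTH_M / self.grid_shape[0]
        dx = MAT_WIDTH_M / self.grid_shape[1]
        return np.array([(rc[1] + 0.5) * dx, (rc[0] + 0.5) * dy])

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(min_row, min_col, max_row, max_col), inclusive."""
        mn = self.pixels.min(axis=0)
        mx = self.pixels.max(axis=0)
        return int(mn[0]), int(mn[1]), int(mx[0]), int(mx[1])

    def pixel_xy(self) -> np.ndarray:
        """(n, 2) pixel-centre coordinates in mat metres (x, y)."""
        dy = MAT_LENGTH_M / self.grid_shape[0]
        dx = MAT_WIDTH_M / self.grid_shape[1]
        x = (self.pixels[:, 1] + 0.5) * dx
        y = (self.pixels[:, 0] + 0.5) * dy
        return np.column_stack([x, y])


@dataclass
class LandmarkSet:
    """Per-frame landmark record extracted from one pressure frame."""

    t: float
    cop_mat: Optional[np.ndarray]  # (x, y) metres, None when no contact
    trunk_angle: float  # rad vs mat long axis, (-pi/2, pi/2]; nan if undefined
    trust: float  # in [0, 1]
    shoulders: Optional[np.ndarray] = None  # (2, 3) [left, right], metres
    head: Optional[np.ndarray] = None  # (x, y) metres
    shoulders_confident: bool = True


# ---------------------------------------------------------------------------
# Pre-processing


def remove_bias(frame: PressureFrame, bias: PressureFrame) -> PressureFrame:
    """Subtract the per-pixel offset matrix, clamping at zero."""
    if frame.grid.shape != bias.grid.shape:
        raise ValueError("frame and bias matrix shapes differ")
    return PressureFrame(frame.t, np.maximum(frame.grid - bias.grid, 0.0))


def suppress_noise(frame: PressureFrame, pixel_threshold: float = 2.0) -> PressureFrame:
    """Zero every pixel whose load is below ``pixel_threshold``."""
    if pixel_threshold < 0:
        raise ValueError("threshold must be >= 0")
    g = frame.grid.copy()
    g[g < pixel_threshold] = 0.0
    return PressureFrame(frame.t, g)


def label_imprints(frame: PressureFrame) -> list[ImprintObject]:
    """Partition nonzero pixels into maximal 8-connected components."""
    labels, n = ndimage.label(frame.grid > 0, structure=_EIGHT_CONN)
    out: list[ImprintObject] = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        pixels = np.column_stack([rows, cols])
        out.append(ImprintObject(pixels, frame.grid.shape, frame.grid[rows, cols]))
    return out


def filter_artifacts(
    objects: Sequence[ImprintObject], min_area: int = 3, min_load: float = 10.0
) -> list[ImprintObject]:
    """Drop small / lightly loaded objects (sensor cross-talk artefacts)."""
    if min_area < 0 or min_load < 0:
        raise ValueError("thresholds must be >= 0")
    return [o for o in objects if o.area >= min_area and o.load >= min_load]


# ---------------------------------------------------------------------------
# Upsampling

_UPSAMPLE_CACHE: dict[tuple, tuple] = {}


def _upsample_operator(shape: tuple[int, int], factor: int) -> tuple:
    """Precompute barycentric interpolation weights raw grid → fine grid.

    Piecewise-linear interpolation over a Delaunay triangulation of the raw
    pixel centres; fine pixels outside the hull of raw centres copy their
    nearest raw pixel.  Cached because the geometry never changes.
    """
    key = (shape, factor)
    if key in _UPSAMPLE_CACHE:
        return _UPSAMPLE_CACHE[key]
    h, w = shape
    yr, xr = pixel_centers(shape)
    src = np.column_stack([np.repeat(yr, w), np.tile(xr, h)])
    tri = Delaunay(src)
    yf, xf = pixel_centers((h * factor, w * factor))
    tgt = np.column_stack([np.repeat(yf, w * factor), np.tile(xf, h * factor)])
    simplex = tri.find_simplex(tgt)
    inside = simplex >= 0
    verts = np.zeros((len(tgt), 3), dtype=int)
    bary = np.zeros((len(tgt), 3))
    s = simplex[inside]
    T = tri.transform[s]
    r = tgt[inside] - T[:, 2]
    b = np.einsum("nij,nj->ni", T[:, :2], r)
    bary[inside] = np.column_stack([b, 1.0 - b.sum(axis=1)])
    verts[inside] = tri.simplices[s]
    # outside the hull: nearest raw pixel (border band of half a raw pixel)
    iy = np.clip(np.round(tgt[:, 0] / (MAT_LENGTH_M / h) - 0.5).astype(int), 0, h - 1)
    ix = np.clip(np.round(tgt[:, 1] / (MAT_WIDTH_M / w) - 0.5).astype(int), 0, w - 1)
    nearest = iy * w + ix
    verts[~inside, 0] = nearest[~inside]
    bary[~inside, 0] = 1.0
    _UPSAMPLE_CACHE[key] = (verts, bary)
    return verts, bary


def upsample(frame: PressureFrame, factor: int = UPSAMPLE_FACTOR) -> PressureFrame:
    """Triangulation-based linear upsampling (55×32 → 165×96 at factor 3)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return PressureFrame(frame.t, frame.grid.copy())
    h, w = frame.grid.shape
    verts, bary = _upsample_operator((h, w), factor)
    flat = frame.grid.ravel()
    fine = (flat[verts] * bary).sum(axis=1)
    return PressureFrame(frame.t, np.maximum(fine.reshape(h * factor, w * factor), 0.0))


# ---------------------------------------------------------------------------
# Landmarks


def center_of_pressure(frame: PressureFrame) -> np.ndarray:
    """Load-weighted centroid of pixel centres, in mat metres (x, y)."""
    total = frame.grid.sum()
    if total <= 0:
        raise NoContactError("zero total load: no contact on the mat")
    y, x = pixel_centers(frame.grid.shape)
    wy = (frame.grid.sum(axis=1) * y).sum() / total
    wx = (frame.grid.sum(axis=0) * x).sum() / total
    return np.array([wx, wy])


class NoContactError(ValueError):
    """Raised when a frame carries no load at all."""


def trunk_imprint(
    frame: PressureFrame,
    cop: np.ndarray,
    radius: float = 0.12,
    min_area: int = 3,
    min_load: float = 10.0,
) -> ImprintObject:
    """Gather the trunk imprint: objects whose centroid lies near the COP.

    The object containing (or nearest to) the COP is always included, so a
    trunk imprint exists whenever the frame is loaded.
    """
    objs = filter_artifacts(label_imprints(frame), min_area, min_load)
    if not objs:
        objs = label_imprints(frame)
    if not objs:
        raise NoContactError("no objects in frame")
    cents = np.array([o.centroid_xy for o in objs])
    d = np.linalg.norm(cents - np.asarray(cop), axis=1)
    keep = d <= radius
    keep[np.argmin(d)] = True
    sel = [o for o, k in zip(objs, keep) if k]
    pixels = np.vstack([o.pixels for o in sel])
    values = np.concatenate([o.values for o in sel])
    return ImprintObject(pixels, frame.grid.shape, values)


def _contrast_stretch(values: np.ndarray, lo_pct: float = 1.0, hi_pct: float = 99.0) -> np.ndarray:
    lo, hi = np.percentile(values, [lo_pct, hi_pct])
    if hi <= lo:
        return np.ones_like(values)
    return np.clip((values - lo) / (hi - lo), 0.0, 1.0)


def _moment_stats(xy: np.ndarray, w: np.ndarray) -> tuple[float, float, float, float]:
    """Weighted central second moments in the (axis=y, lateral=x) basis."""
    w = w / w.sum()
    mean = (xy * w[:, None]).sum(axis=0)
    d = xy - mean
    u = d[:, 1]  # along the mat long axis
    v = d[:, 0]  # across
    muu = float((w * u * u).sum())
    mvv = float((w * v * v).sum())
    muv = float((w * u * v).sum())
    lam1 = 0.5 * ((muu + mvv) + np.hypot(muu - mvv, 2 * muv))
    return muu, mvv, muv, lam1


@dataclass
class TrustModel:
    """Monotone trust in the imprint-derived trunk orientation.

    Product of three unit-clipped linear ramps: imprint load (saturating at
    ``load_ref``), imprint length (major-axis length, saturating at
    ``length_ref``) and COP distance from the mat centre (zero trust at
    ``dist_ref``).
    """

    load_ref: float = 500.0  # device units
    length_ref: float = 0.10  # m
    dist_ref: float = 0.30  # m

    def __call__(self, load: float, length: float, dist_to_center: float) -> float:
        s = lambda x: float(np.clip(x, 0.0, 1.0))
        return (
            s(load / self.load_ref)
            * s(length / self.length_ref)
            * s(1.0 - dist_to_center / self.dist_ref)
        )


DEFAULT_TRUST = TrustModel()


def imprint_orientation(
    imprint: ImprintObject,
    frame: PressureFrame,
    trust_model: TrustModel = DEFAULT_TRUST,
) -> tuple[float, float]:
    """Trunk-imprint orientation from load-weighted central image moments.

    Returns ``(angle, trust)``; the angle is measured from the mat long
    axis in (−π/2, π/2] via ``0.5·atan2(2µ11, µ20 − µ02)`` after a 1–99
    percentile contrast stretch.  An isotropic imprint has no principal
    axis: the angle is NaN and trust is forced to 0.
    """
    if imprint.area == 0:
        raise ValueError("empty imprint")
    w = _contrast_stretch(imprint.values) * imprint.values
    if w.sum() <= 0:
        w = imprint.values
    xy = imprint.pixel_xy()
    muu, mvv, muv, lam1 = _moment_stats(xy, w)
    if abs(muu - mvv) < 1e-12 and abs(muv) < 1e-12:
        return float("nan"), 0.0
    angle = 0.5 * np.arctan2(2.0 * muv, muu - mvv)
    if angle <= -np.pi / 2:
        angle += np.pi
    length = 4.0 * np.sqrt(lam1)  # ±2σ ellipse major-axis length
    center = np.array([MAT_WIDTH_M / 2, MAT_LENGTH_M / 2])
    dist = float(np.linalg.norm(imprint.centroid_xy - center))
    trust = trust_model(imprint.load, length, dist)
    return float(angle), trust


@dataclass
class ShoulderGeometry:
    """Pre-set doll/infant shoulder placement relative to the trunk imprint."""

    half_separation: float = 0.06  # m, lateral offset from the trunk axis
    cranial_offset: float = 0.10  # m, from COP toward the head
    height: float = 0.05  # m, shoulder height above the mat when supine
    peak_prominence_frac: float = 0.20  # double-histogram peak gate


def detect_shoulders(
    imprint: ImprintObject,
    frame: PressureFrame,
    trunk_angle: float,
    trunk_rotation: np.ndarray,
    geometry: ShoulderGeometry | None = None,
    trust: float = 1.0,
) -> tuple[np.ndarray, bool]:
    """Place the (left, right) shoulder points in the mat frame.

    Base placement is symmetric about the trunk axis at the cranial end,
    using pre-set anthropometric distances.  The trunk rotation matrix
    (mat←trunk) disambiguates the cranial direction and supplies the roll
    angle: rolling tilts the shoulder line, lowering the loaded-side
    shoulder and shrinking the projected lateral separation.  When the
    cranial band of the imprint shows two sufficiently prominent load
    peaks (double-histogram analysis) their lateral positions override the
    pre-set offsets.  With an unreliable imprint (``trust`` below 0.5 or
    undefined angle) the purely geometric placement is returned flagged
    low-confidence.

    Returns ``(shoulders (2,3) [left, right] in metres, high_confidence)``.
    """
    geometry = geometry or ShoulderGeometry()
    R = np.asarray(trunk_rotation, dtype=float)
    cop = imprint.centroid_xy
    reliable = trust >= 0.5 and np.isfinite(trunk_angle)
    if reliable:
        axis = np.array([np.sin(trunk_angle), np.cos(trunk_angle)])
    else:
        axis = R[:2, 1]
        n = np.linalg.norm(axis)
        axis = axis / n if n > 1e-6 else np.array([0.0, 1.0])
    # cranial disambiguation from the trunk IMU's caudal→cranial (y) axis
    if float(axis @ R[:2, 1]) < 0:
        axis = -axis
    # baby's left is the +x side of the trunk frame projected onto the mat
    left2 = np.array([axis[1], -axis[0]])
    if float(left2 @ R[:2, 0]) < 0:
        left2 = -left2
    roll = float(np.arctan2(R[2, 0], R[0, 0] * left2[0] + R[1, 0] * left2[1]))
    mid = cop + geometry.cranial_offset * axis
    half = geometry.half_separation
    lat = half * np.cos(roll)
    z_left = geometry.height + half * np.sin(roll)
    z_right = geometry.height - half * np.sin(roll)
    left = np.array([*(mid + lat * left2), max(z_left, 0.0)])
    right = np.array([*(mid - lat * left2), max(z_right, 0.0)])
    if reliable:
        override = _shoulder_histogram_override(
            imprint, axis, left2, cop, geometry, mid
        )
        if override is not None:
            lat_l, lat_r = override
            left[:2] = mid + lat_l * left2
            right[:2] = mid + lat_r * left2
    return np.vstack([left, right]), reliable


def _shoulder_histogram_override(
    imprint: ImprintObject,
    axis: np.ndarray,
    left2: np.ndarray,
    cop: np.ndarray,
    geometry: ShoulderGeometry,
    mid: np.ndarray,
) -> Optional[tuple[float, float]]:
    """Double-histogram analysis of the cranial imprint band.

    Projects the cranial quarter of the imprint onto the lateral axis and
    looks for exactly two prominent load peaks; returns their signed
    lateral coordinates (toward baby-left positive) or None.
    """
    xy = imprint.pixel_xy()
    s_ax = (xy - cop) @ axis
    hi = s_ax.max()
    if hi <= 0:
        return None
    band = s_ax >= 0.5 * hi
    if band.sum() < 4:
        return None
    s_lat = (xy[band] - mid) @ left2
    wts = imprint.values[band]
    pitch = MAT_WIDTH_M / imprint.grid_shape[1]
    bins = np.arange(s_lat.min() - pitch, s_lat.max() + 2 * pitch, pitch)
    if len(bins) < 6:
        return None
    hist, edges = np.histogram(s_lat, bins=bins, weights=wts)
    if hist.max() <= 0:
        return None
    peaks, _ = find_peaks(hist, prominence=geometry.peak_prominence_frac * hist.max())
    if len(peaks) != 2:
        return None
    centers = 0.5 * (edges[:-1] + edges[1:])
    lat_a, lat_b = centers[peaks]
    if abs(lat_a - lat_b) < 2 * pitch:
        return None
    return (max(lat_a, lat_b), min(lat_a, lat_b))


@dataclass
class HeadDetectorParams:
    v_head_max: float = 0.5  # m/s, plausibility gate on head displacement
    cone_half_angle: float = np.deg2rad(45.0)
    min_area: int = 3
    min_load: float = 10.0


def detect_head(
    frame: PressureFrame,
    shoulders: np.ndarray,
    previous_head: Optional[np.ndarray] = None,
    dt: float = 1.0 / 30.0,
    params: HeadDetectorParams | None = None,
) -> Optional[np.ndarray]:
    """Locate the head imprint cranial of the shoulder line.

    Looks for a separate labelled object inside a search cone about the
    trunk axis on the cranial side; when head and trunk merge into one
    object, the load profile along the trunk axis is split at its valley
    (neck) and the cranial part's centroid is used.  A candidate implying
    an implausible head speed w.r.t. ``previous_head`` is rejected in
    favour of the tracked position.  Returns ``(x, y)`` metres or None.
    """
    params = params or HeadDetectorParams()
    shoulders = np.asarray(shoulders, dtype=float)
    mid = shoulders[:2, :2].mean(axis=0)
    try:
        cop = center_of_pressure(frame)
    except NoContactError:
        return previous_head
    cranial = mid - cop
    n = np.linalg.norm(cranial)
    if n < 1e-9:
        return previous_head
    cranial = cranial / n
    objs = filter_artifacts(label_imprints(frame), params.min_area, params.min_load)
    cand: Optional[np.ndarray] = None
    best_load = 0.0
    merged_obj: Optional[ImprintObject] = None
    for o in objs:
        c = o.centroid_xy
        d = c - mid
        dist = np.linalg.norm(d)
        pix_ax = (o.pixel_xy() - mid) @ cranial
        if pix_ax.min() < 0 < pix_ax.max():
            # object straddles the shoulder line: merged head+trunk candidate
            if merged_obj is None or o.load > merged_obj.load:
                merged_obj = o
            continue
        if dist < 1e-9 or float(d @ cranial) <= 0:
            continue
        ang = np.arccos(np.clip(float(d @ cranial) / dist, -1.0, 1.0))
        if ang <= params.cone_half_angle and o.load > best_load:
            best_load = o.load
            cand = c
    if cand is None and merged_obj is not None:
        cand = _split_merged_head(merged_obj, mid, cranial)
    if cand is None:
        return previous_head
    if previous_head is not None:
        speed = np.linalg.norm(cand - previous_head) / dt
        if speed > params.v_head_max:
            return previous_head
    return cand


def _split_merged_head(
    obj: ImprintObject, mid: np.ndarray, cranial: np.ndarray
) -> Optional[np.ndarray]:
    """Split a merged head+trunk object at the neck valley of its axial
    load profile; return the cranial part's load-weighted centroid."""
    xy = obj.pixel_xy()
    s = (xy - mid) @ cranial
    pitch = MAT_LENGTH_M / obj.grid_shape[0]
    bins = np.arange(s.min() - pitch, s.max() + 2 * pitch, pitch)
    if len(bins) < 5:
        return None
    hist, edges = np.histogram(s, bins=bins, weights=obj.values)
    valleys, _ = find_peaks(-hist, prominence=0.1 * hist.max())
    centers = 0.5 * (edges[:-1] + edges[1:])
    valleys = [v for v in valleys if centers[v] > 0]
    if not valleys:
        return None
    cut = centers[valleys[0]]
    sel = s > cut
    if not np.any(sel):
        return None
    w = obj.values[sel]
    return (xy[sel] * (w / w.sum())[:, None]).sum(axis=0)


def render_overlay(
    frame: PressureFrame, landmarks: LandmarkSet, path: str
) -> None:
    """Write a PNG debug overlay: pressure image, COP, trunk axis,
    shoulders, head."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 6))
    ax.imshow(
        frame.grid,
        origin="lower",
        extent=(0, MAT_WIDTH_M, 0, MAT_LENGTH_M),
        cmap="viridis",
        aspect="equal",
    )
    if landmarks.cop_mat is not None:
        cx, cy = landmarks.cop_mat
        ax.plot(cx, cy, "wo", ms=8, mfc="none", label="COP")
        if np.isfinite(landmarks.trunk_angle):
            ax.plot(
                [cx - 0.1 * np.sin(landmarks.trunk_angle), cx + 0.1 * np.sin(landmarks.trunk_angle)],
                [cy - 0.1 * np.cos(landmarks.trunk_angle), cy + 0.1 * np.cos(landmarks.trunk_angle)],
                "r-",
                label="trunk axis",
            )
    if landmarks.shoulders is not None:
        ax.plot(landmarks.shoulders[:, 0], landmarks.shoulders[:, 1], "mo", label="shoulders")
    if landmarks.head is not None:
        ax.plot(landmarks.head[0], landmarks.head[1], "c^", label="head")
    ax.legend(loc="upper right", fontsize=7)
    ax.set_xlabel("x [m]")
    ax.set_ylabel("y [m]")
    fig.savefig(path, dpi=120)
    plt.close(fig)
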
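"""Session persistence and multi-rate synchronization.

A *session* bundles the 30 Hz pressure-frame stream, up to six 100 Hz IMU
streams (REF, TRUNK, UA_L, UA_R, FA_L, FA_R) and optional 100 Hz reference
marker trajectories.  Two containers are supported: a single HDF5 file
(layout ``/pressure/{t,frames}``, ``/imu/<label>/{t,gyro,acc,mag}``,
``/markers/<label>/{t,xyz}``, ``/meta`` attributes) and a directory of
CSV files for interchange (one file per stream; pressure frames flattened
row-major).  Timestamps are seconds from session start.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .motor_metrics import MetricsReport
from .pressure_image import MAT_LENGTH_M, MAT_WIDTH_M, RAW_SHAPE

IMU_LABELS = ("REF", "TRUNK", "UA_L", "UA_R", "FA_L", "FA_R")

__all__ = [
    "ImuStream",
    "PressureStream",
    "MarkerStream",
    "SessionMeta",
    "SessionBundle",
    "read_session",
    "write_session",
    "synchronize",
    "write_report",
    "read_report",
]


class SessionValidationError(ValueError):
    pass


def _check_monotone(t: np.ndarray, what: str) -> None:
    if len(t) and np.any(np.diff(t) <= 0):
        raise SessionValidationError(f"{what}: timestamps not strictly increasing")


@dataclass
class ImuStream:
    """100 Hz inertial/magnetic samples: gyro [rad/s], specific force
    [m/s²], magnetic field [unit vectors]."""

    t: np.ndarray
    gyro: np.ndarray
    acc: np.ndarray
    mag: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("gyro", "acc", "mag"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (len(self.t), 3):
                raise SessionValidationError(f"IMU {name} must be (n, 3)")
            if not np.all(np.isfinite(v)):
                raise SessionValidationError(f"IMU {name} contains non-finite values")
            setattr(self, name, v)
        _check_monotone(self.t, "IMU stream")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class PressureStream:
    """30 Hz pressure frames, (n, 55, 32) non-negative loads."""

    t: np.ndarray
    frames: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] != len(self.t):
            raise SessionValidationError("pressure frames must be (n, H, W)")
        if np.any(self.frames < 0):
            raise SessionValidationError("pressure frames contain negative loads")
        _check_monotone(self.t, "pressure stream")

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class MarkerStream:
    t: np.ndarray
    xyz: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (len(self.t), 3):
            raise SessionValidationError("marker stream must be (n, 3)")
        _check_monotone(self.t, "marker stream")


@dataclass
class SessionMeta:
    l_ua: float = 0.07
    l_fa: float = 0.07
    mat_length: float = MAT_LENGTH_M
    mat_width: float = MAT_WIDTH_M
    pressure_bias: Optional[np.ndarray] = None  # (55, 32) offset matrix

    def __post_init__(self) -> None:
        if self.l_ua <= 0 or self.l_fa <= 0:
            raise SessionValidationError("segment lengths must be positive")


@dataclass
class SessionBundle:
    pressure: PressureStream
    imu: dict[str, ImuStream] = field(default_factory=dict)
    markers: dict[str, MarkerStream] = field(default_factory=dict)
    meta: SessionMeta = field(default_factory=SessionMeta)

    def __post_init__(self) -> None:
        for label in self.imu:
            if label not in IMU_LABELS:
                raise SessionValidationError(f"unknown IMU label {label!r}")
        if self.time_window()[1] <= self.time_window()[0]:
            raise SessionValidationError("streams share no common time window")

    def time_window(self) -> tuple[float, float]:
        starts = [self.pressure.t[0]] + [s.t[0] for s in self.imu.values()]
        ends = [self.pressure.t[-1]] + [s.t[-1] for s in self.imu.values()]
        for m in self.markers.values():
            starts.append(m.t[0])
            ends.append(m.t[-1])
        return max(starts), min(ends)


# ---------------------------------------------------------------------------
# HDF5 container


def write_session(bundle: SessionBundle, path: str | Path) -> None:
    """Write a session to a single HDF5 file (lossless round-trip)."""
    with h5py.File(path, "w") as fh:
        g = fh.create_group("pressure")
        g.create_dataset("t", data=bundle.pressure.t)
        g.create_dataset("frames", data=bundle.pressure.frames)
        gi = fh.create_group("imu")
        for label, s in bundle.imu.items():
            gg = gi.create_group(label)
            gg.create_dataset("t", data=s.t)
            gg.create_dataset("gyro", data=s.gyro)
            gg.create_dataset("acc", data=s.acc)
            gg.create_dataset("mag", data=s.mag)
        if bundle.markers:
            gm = fh.create_group("markers")
            for label, s in bundle.markers.items():
                gg = gm.create_group(label)
                gg.create_dataset("t", data=s.t)
                gg.create_dataset("xyz", data=s.xyz)
        meta = fh.create_group("meta")
        meta.attrs["l_ua"] = bundle.meta.l_ua
        meta.attrs["l_fa"] = bundle.meta.l_fa
        meta.attrs["mat_length"] = bundle.meta.mat_length
        meta.attrs["mat_width"] = bundle.meta.mat_width
        if bundle.meta.pressure_bias is not None:
            meta.create_dataset("pressure_bias", data=bundle.meta.pressure_bias)


def _read_session_h5(path: str | Path) -> SessionBundle:
    with h5py.File(path, "r") as fh:
        pressure = PressureStream(fh["pressure/t"][...], fh["pressure/frames"][...])
        imu = {}
        for label in fh.get("imu", {}):
            g = fh[f"imu/{label}"]
            imu[label] = ImuStream(g["t"][...], g["gyro"][...], g["acc"][...], g["mag"][...])
        markers = {}
        if "markers" in fh:
            for label in fh["markers"]:
                g = fh[f"markers/{label}"]
                markers[label] = MarkerStream(g["t"][...], g["xyz"][...])
        meta = SessionMeta(
            l_ua=float(fh["meta"].attrs["l_ua"]),
            l_fa=float(fh["meta"].attrs["l_fa"]),
            mat_length=float(fh["meta"].attrs["mat_length"]),
            mat_width=float(fh["meta"].attrs["mat_width"]),
            pressure_bias=fh["meta/pressure_bias"][...] if "pressure_bias" in fh["meta"] else None,
        )
    return SessionBundle(pressure, imu, markers, meta)


# ---------------------------------------------------------------------------
# CSV interchange


def _parse_error(path: str | Path, line: int, msg: str) -> SessionValidationError:
    return SessionValidationError(f"{path}:{line}: {msg}")


def _read_csv_matrix(path: str | Path, n_cols: int) -> np.ndarray:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise _parse_error(path, 1, "empty file")
        for i, row in enumerate(reader, start=2):
            if len(row) != n_cols:
                raise _parse_error(path, i, f"expected {n_cols} columns, got {len(row)}")
            try:
                rows.append([float(v) for v in row])
            except ValueError as exc:
                raise _parse_error(path, i, f"malformed number: {exc}")
    return np.asarray(rows, dtype=float)


def write_session_csv(bundle: SessionBundle, directory: str | Path) -> None:
    """Write a session as one CSV per stream into ``directory``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    h, w = bundle.pressure.frames.shape[1:]
    with open(d / "pressure.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["t"] + [f"p{i:04d}" for i in range(h * w)])
        for t, frame in zip(bundle.pressure.t, bundle.pressure.frames):
            wr.writerow([repr(float(t))] + [repr(float(v)) for v in frame.ravel()])
    for label, s in bundle.imu.items():
        with open(d / f"imu_{label}.csv", "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["t", "gx", "gy", "gz", "ax", "ay", "az", "mx", "my", "mz"])
            data = np.column_stack([s.t, s.gyro, s.acc, s.mag])
            for row in data:
                wr.writerow([repr(float(v)) for v in row])
    for label, s in bundle.markers.items():
        with open(d / f"markers_{label}.csv", "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["t", "x", "y", "z"])
            for row in np.column_stack([s.t, s.xyz]):
                wr.writerow([repr(float(v)) for v in row])
    with open(d / "meta.json", "w") as fh:
        json.dump({"l_ua": bundle.meta.l_ua, "l_fa": bundle.meta.l_fa}, fh)


def _read_session_csv(directory: str | Path, config=None) -> SessionBundle:
    d = Path(directory)
    h, w = RAW_SHAPE
    ppath = d / "pressure.csv"
    pdata = _read_csv_matrix(ppath, 1 + h * w)
    frames = pdata[:, 1:].reshape(-1, h, w)
    if np.any(frames < 0):
        raise SessionValidationError(f"{ppath}: negative pressure loads")
    pressure = PressureStream(pdata[:, 0], frames)
    imu = {}
    for label in IMU_LABELS:
        f = d / f"imu_{label}.csv"
        if f.exists():
            m = _read_csv_matrix(f, 10)
            imu[label] = ImuStream(m[:, 0], m[:, 1:4], m[:, 4:7], m[:, 7:10])
    markers = {}
    for f in sorted(d.glob("markers_*.csv")):
        label = f.stem[len("markers_"):]
        m = _read_csv_matrix(f, 4)
        markers[label] = MarkerStream(m[:, 0], m[:, 1:4])
    meta = SessionMeta()
    mpath = d / "meta.json"
    if mpath.exists():
        with open(mpath) as fh:
            raw = json.load(fh)
        meta = SessionMeta(l_ua=raw.get("l_ua", 0.07), l_fa=raw.get("l_fa", 0.07))
    if config is not None:
        meta.l_ua = getattr(config, "l_ua", meta.l_ua)
        meta.l_fa = getattr(config, "l_fa", meta.l_fa)
    return SessionBundle(pressure, imu, markers, meta)


def read_session(path: str | Path, config=None) -> SessionBundle:
    """Read a session from an HDF5 file or a CSV directory."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(path)
    if p.is_dir():
        return _read_session_csv(p, config)
    return _read_session_h5(p)


# ---------------------------------------------------------------------------
# Synchronization


def synchronize(bundle: SessionBundle) -> SessionBundle:
    """Resample every stream onto the common 100 Hz IMU timeline.

    The common window is the intersection of all stream spans; IMU and
    marker signals are linearly interpolated onto the (cropped) timeline
    of the first IMU stream, pressure frames are carried by zero-order
    hold.  No sample outside a source's own span is ever invented.
    """
    if not bundle.imu:
        raise SessionValidationError("cannot synchronize without an IMU stream")
    t0, t1 = bundle.time_window()
    if t1 <= t0:
        raise SessionValidationError("streams share no common time window")
    base = next(iter(bundle.imu.values())).t
    tl = base[(base >= t0) & (base <= t1)]
    if len(tl) < 2:
        raise SessionValidationError("common window too short")

    def interp_cols(t_src, arr):
        return np.column_stack([np.interp(tl, t_src, arr[:, j]) for j in range(arr.shape[1])])

    imu = {
        label: ImuStream(tl, interp_cols(s.t, s.gyro), interp_cols(s.t, s.acc), interp_cols(s.t, s.mag))
        for label, s in bundle.imu.items()
    }
    idx = np.clip(np.searchsorted(bundle.pressure.t, tl, side="right") - 1, 0, None)
    pressure = PressureStream(tl, bundle.pressure.frames[idx])
    markers = {
        label: MarkerStream(tl, interp_cols(s.t, s.xyz)) for label, s in bundle.markers.items()
    }
    return SessionBundle(pressure, imu, markers, bundle.meta)


# ---------------------------------------------------------------------------
# Reports


def write_report(report: MetricsReport, path: str | Path) -> None:
    """Write a metrics report as JSON plus a CSV parameter table."""
    p = Path(path)
    with open(p, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    with open(p.with_suffix(".csv"), "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["parameter", "value", "units", "placement"])
        for name, units in MetricsReport.UNITS.items():
            v = getattr(report, name)
            wr.writerow([name, "insufficient data" if v is None else v, units, report.placement])


def read_report(path: str | Path) -> MetricsReport:
    with open(path) as fh:
        return MetricsReport.from_dict(json.load(fh))
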
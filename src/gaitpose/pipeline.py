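"""Tracking output stage: smoothing, 30 fps CSV export, score gating, angle series.

Tracked coordinates are kept twice per frame — raw, and low-pass filtered
with a zero-phase second-order Butterworth (6 Hz default, a standard choice
for human-gait kinematics).  Joint angles are computed from the smoothed
coordinates, and every joint carries a reliability flag: it is trusted only
when the confidence ("AI score") of each keypoint defining it reaches the
threshold, 0.7 by default.

The CSV dialect (this package's documented standard): optional ``#``-prefixed
``key = value`` comment lines, then a header row, then one row per frame with
``frame,time_s``, seven columns per keypoint
(``x_raw,y_raw,z_raw,x_smooth,y_smooth,z_smooth,score``) in skeleton order,
and a trailing ``body_score`` — 2 + 24*7 + 1 = 171 columns.  Values are
written with 9 significant digits (lossless round trip at that precision);
missing coordinates are empty fields, never zeros.  LF line endings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .skeleton import (
    JOINT_KEYPOINTS,
    JointAngles,
    KeypointID,
    MotionSequence,
    N_KEYPOINTS,
    Pose3D,
    DegeneratePoseError,
    InvalidPoseError,
    limb_angles,
)

__all__ = [
    "TrackingRecord",
    "AngleSeries",
    "TooShortError",
    "CsvParseError",
    "lowpass_smooth",
    "resample",
    "records_from_sequence",
    "angle_series",
    "write_csv",
    "read_csv",
]


class TooShortError(ValueError):
    """The series is shorter than the filter warm-up length."""


class CsvParseError(ValueError):
    """A tracking CSV file is malformed; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class TrackingRecord:
    """One frame of tracking output: raw and smoothed coordinates plus scores."""

    frame_index: int
    time_s: float
    raw: np.ndarray  # (24, 3); NaN rows mark missing keypoints
    smoothed: np.ndarray  # (24, 3)
    scores: np.ndarray  # (24,) in [0, 1]
    body_score: float = 1.0

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float).reshape(N_KEYPOINTS, 3)
        self.smoothed = np.asarray(self.smoothed, dtype=float).reshape(N_KEYPOINTS, 3)
        self.scores = np.asarray(self.scores, dtype=float).reshape(N_KEYPOINTS)
        if ((self.scores < 0) | (self.scores > 1)).any() or not (0 <= self.body_score <= 1):
            raise ValueError("AI scores must lie in [0, 1]")


_FILTER_ORDER = 2


def _design(fps: float, cutoff: float):
    if fps <= 2.0 * cutoff:
        raise ValueError(f"fps ({fps}) must exceed twice the cutoff ({cutoff} Hz)")
    return butter(_FILTER_ORDER, cutoff / (fps / 2.0))


def lowpass_smooth(series: np.ndarray, fps: float, cutoff: float = 6.0) -> np.ndarray:
    """Zero-phase second-order low-pass along axis 0; length preserved.

    Applied forward and backward (``filtfilt``), so the effective magnitude
    response is the square of the Butterworth response and the phase delay is
    zero — peaks in the gait traces stay where they happened.
    """
    series = np.asarray(series, dtype=float)
    b, a = _design(fps, cutoff)
    padlen = 3 * max(len(a), len(b))
    if series.shape[0] <= padlen:
        raise TooShortError(
            f"series of length {series.shape[0]} is shorter than the "
            f"filter warm-up ({padlen + 1} samples)"
        )
    return filtfilt(b, a, series, axis=0)


def resample(sequence: MotionSequence, to_fps: float) -> MotionSequence:
    """Decimate a sequence to a lower frame rate (e.g. 60 -> 30 fps).

    Only integer decimation is supported and upsampling is refused; apply
    :func:`lowpass_smooth` first when the decimated rate approaches twice the
    signal bandwidth.  Timestamps and frame indices are regenerated.
    """
    if to_fps > sequence.fps:
        raise ValueError("resample only decimates; requested fps exceeds source fps")
    ratio = sequence.fps / to_fps
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(f"source fps {sequence.fps} is not an integer multiple of {to_fps}")
    step = int(round(ratio))
    frames = [
        Pose3D(f.coords.copy(), frame_index=i, timestamp=i / to_fps)
        for i, f in enumerate(sequence.frames[::step])
    ]
    return MotionSequence(frames, to_fps)


def records_from_sequence(
    sequence: MotionSequence,
    confidences: np.ndarray | None = None,
    cutoff: float | None = 6.0,
) -> list[TrackingRecord]:
    """Build tracking records from decoded poses, smoothing each coordinate.

    ``confidences`` is an (n_frames, 24) score array (defaults to all ones);
    ``cutoff=None`` disables filtering (smoothed == raw).
    """
    coords = sequence.as_array()
    n = coords.shape[0]
    if confidences is None:
        confidences = np.ones((n, N_KEYPOINTS))
    confidences = np.asarray(confidences, dtype=float)
    if cutoff is None:
        smooth = coords.copy()
    else:
        smooth = lowpass_smooth(coords.reshape(n, -1), sequence.fps, cutoff).reshape(coords.shape)
    return [
        TrackingRecord(
            frame_index=f.frame_index,
            time_s=f.timestamp,
            raw=coords[i],
            smoothed=smooth[i],
            scores=confidences[i],
            body_score=float(confidences[i].min()),
        )
        for i, f in enumerate(sequence.frames)
    ]


@dataclass
class AngleSeries:
    """Joint-angle time series with per-joint reliability flags."""

    time_s: np.ndarray  # (n,)
    angles: pd.DataFrame  # (n, 8), columns = JointAngles.JOINTS, degrees
    reliable: pd.DataFrame  # (n, 8) bool, AI-score gate at the threshold
    threshold: float = 0.7

    def __len__(self) -> int:
        return len(self.angles)


def angle_series(
    records: Sequence[TrackingRecord],
    threshold: float = 0.7,
    convention: str = "flexion",
    use_smoothed: bool = True,
) -> AngleSeries:
    """Joint angles over time, gated by per-keypoint AI scores.

    A joint is flagged reliable on a frame when the minimum score of its
    defining keypoints reaches ``threshold``.  Frames whose geometry is
    degenerate (zero-length limb vectors, missing keypoints) yield NaN
    angles and are flagged unreliable.
    """
    rows, flags, times = [], [], []
    joints = JointAngles.JOINTS
    for rec in records:
        coords = rec.smoothed if use_smoothed else rec.raw
        times.append(rec.time_s)
        try:
            ja = limb_angles(Pose3D(coords, rec.frame_index, rec.time_s), convention)
            rows.append([getattr(ja, j) for j in joints])
            ok = [
                min(rec.scores[int(kp)] for kp in JOINT_KEYPOINTS[j]) >= threshold
                for j in joints
            ]
        except (DegeneratePoseError, InvalidPoseError):
            rows.append([math.nan] * len(joints))
            ok = [False] * len(joints)
        flags.append(ok)
    return AngleSeries(
        time_s=np.asarray(times),
        angles=pd.DataFrame(rows, columns=list(joints)),
        reliable=pd.DataFrame(flags, columns=list(joints)),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# CSV dialect
# ---------------------------------------------------------------------------


def _columns() -> list[str]:
    cols = ["frame", "time_s"]
    for kp in KeypointID:
        cols += [f"{kp.name}_{axis}_{kind}" for kind in ("raw", "smooth") for axis in "xyz"]
        cols.append(f"{kp.name}_score")
    cols.append("body_score")
    return cols


def _fmt(v: float) -> str:
    return "" if not np.isfinite(v) else f"{v:.9g}"


def write_csv(
    records: Sequence[TrackingRecord],
    path: str | Path,
    meta: dict | None = None,
) -> Path:
    """Write tracking records in the package CSV dialect (byte-deterministic)."""
    path = Path(path)
    lines = []
    for key, val in (meta or {}).items():
        lines.append(f"# {key} = {val}")
    lines.append(",".join(_columns()))
    for rec in records:
        fields = [str(int(rec.frame_index)), _fmt(rec.time_s)]
        for kp in range(N_KEYPOINTS):
            fields += [_fmt(v) for v in rec.raw[kp]]
            fields += [_fmt(v) for v in rec.smoothed[kp]]
            fields.append(_fmt(rec.scores[kp]))
        fields.append(_fmt(rec.body_score))
        lines.append(",".join(fields))
    path.write_text("\n".join(lines) + "\n", newline="\n")
    return path


def read_csv(path: str | Path) -> tuple[list[TrackingRecord], dict]:
    """Parse a tracking CSV; returns (records, metadata from comment lines)."""
    path = Path(path)
    expected = _columns()
    meta: dict[str, str] = {}
    records: list[TrackingRecord] = []
    header_seen = False
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            fields = line.split(",")
            if not header_seen:
                if fields != expected:
                    raise CsvParseError(
                        f"unexpected header ({len(fields)} columns, expected {len(expected)})",
                        lineno,
                    )
                header_seen = True
                continue
            if len(fields) != len(expected):
                raise CsvParseError(
                    f"expected {len(expected)} fields, found {len(fields)}", lineno
                )
            try:
                frame = int(fields[0])
                vals = [float(f) if f != "" else math.nan for f in fields[1:]]
            except ValueError as exc:
                raise CsvParseError(str(exc), lineno) from None
            block = np.asarray(vals[1:-1]).reshape(N_KEYPOINTS, 7)
            records.append(
                TrackingRecord(
                    frame_index=frame,
                    time_s=vals[0],
                    raw=block[:, 0:3],
                    smoothed=block[:, 3:6],
                    scores=np.nan_to_num(block[:, 6], nan=0.0),
                    body_score=0.0 if math.isnan(vals[-1]) else vals[-1],
                )
            )
    if not header_seen:
        raise CsvParseError("missing header row", 1)
    return records, meta
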
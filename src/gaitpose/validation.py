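"""Cross-validation against optical motion capture.

A reference system (e.g. an optical marker system) and the tracker observe
the same movement in fundamentally different coordinate systems — global
lab coordinates versus body-relative, split-scaled coordinates.  No spatial
registration between them is meaningful, so validation works per matched
axis: the two streams are aligned on the time axis by cross-correlation,
then for each keypoint and coordinate the per-axis means and the Pearson
product-moment correlation are tabulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .skeleton import KeypointID
from .pipeline import TrackingRecord

__all__ = [
    "ReferenceTrack",
    "MappingError",
    "UndefinedCorrelationError",
    "read_reference",
    "write_reference",
    "align_time",
    "pearson",
    "comparison_table",
]

_AXES = ("x", "y", "z")


class MappingError(ValueError):
    """Reference labels could not be mapped onto the 24-keypoint skeleton."""


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (constant input or too few samples)."""


@dataclass
class ReferenceTrack:
    """Labeled marker trajectories at a uniform sampling rate."""

    markers: dict[str, np.ndarray]  # name -> (n, 3), meters
    fps: float
    units: str = "m"

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        lengths = {m.shape[0] for m in self.markers.values()}
        if len(lengths) > 1:
            raise ValueError("all marker series must have the same length")

    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0] if self.markers else 0

    def mapped_keypoints(self) -> dict[KeypointID, np.ndarray]:
        """Markers whose (case-insensitive) labels name skeleton keypoints."""
        names = {k.name: k for k in KeypointID}
        out = {}
        unmatched = []
        for label, series in self.markers.items():
            kp = names.get(label.strip().lower())
            if kp is None:
                unmatched.append(label)
            else:
                out[kp] = series
        if not out:
            raise MappingError(f"no reference labels match keypoints: {unmatched}")
        return out


def _to_meters(arr: np.ndarray, units: str) -> np.ndarray:
    scale = {"m": 1.0, "mm": 1e-3, "cm": 1e-2}.get(units.lower())
    if scale is None:
        raise ValueError(f"unknown units {units!r}")
    return arr * scale


def read_reference(path: str | Path, format: str | None = None) -> ReferenceTrack:
    """Read marker trajectories from CSV or TRC; coordinates come back in meters.

    CSV: ``#``-comment lines may carry ``fps`` and ``units``; the header is
    ``time_s`` followed by ``<name>_x,<name>_y,<name>_z`` triples.  TRC is
    the standard tab-separated marker format (units taken from its header).
    """
    path = Path(path)
    if format is None:
        format = "trc" if path.suffix.lower() == ".trc" else "csv"
    if format == "trc":
        return _read_trc(path)
    if format != "csv":
        raise ValueError(f"unknown reference format {format!r}")

    meta = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "=" in line:
                key, _, val = line.lstrip("# ").partition("=")
                meta[key.strip()] = val.strip()
    df = pd.read_csv(path, comment="#")
    fps = float(meta.get("fps", 0)) or _infer_fps(df["time_s"].to_numpy())
    units = meta.get("units", "m")
    markers = {}
    for col in df.columns:
        if col.endswith("_x"):
            name = col[:-2]
            arr = df[[f"{name}_{a}" for a in _AXES]].to_numpy(dtype=float)
            markers[name] = _to_meters(arr, units)
    return ReferenceTrack(markers, fps=fps, units="m")


def _infer_fps(t: np.ndarray) -> float:
    dt = np.diff(t)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("cannot infer fps from non-uniform timestamps")
    return 1.0 / float(dt[0])


def _read_trc(path: Path) -> ReferenceTrack:
    lines = Path(path).read_text().splitlines()
    if len(lines) < 6:
        raise ValueError("truncated TRC file")
    header = dict(zip(lines[1].split("\t"), lines[2].split("\t")))
    fps = float(header.get("DataRate", 0) or header.get("CameraRate", 0))
    units = header.get("Units", "mm")
    names = [n for n in lines[3].split("\t")[2:] if n]
    data_rows = [
        ln.split("\t")
        for ln in lines[5:]
        if ln.strip() and ln.split("\t")[0].strip().isdigit()
    ]
    data = np.asarray(
        [[float(f) if f else np.nan for f in row] for row in data_rows], dtype=float
    )
    markers = {}
    for mi, name in enumerate(names):
        block = data[:, 2 + 3 * mi : 5 + 3 * mi]
        markers[name] = _to_meters(block, units)
    return ReferenceTrack(markers, fps=fps, units="m")


def write_reference(track: ReferenceTrack, path: str | Path, format: str = "csv") -> Path:
    """Write a reference track (CSV dialect or minimal standard TRC)."""
    path = Path(path)
    n = track.n_frames()
    if format == "csv":
        cols = ["time_s"]
        arrays = [np.arange(n) / track.fps]
        for name, series in track.markers.items():
            for ai, a in enumerate(_AXES):
                cols.append(f"{name}_{a}")
                arrays.append(series[:, ai])
        lines = [f"# fps = {track.fps:.9g}", "# units = m", ",".join(cols)]
        for i in range(n):
            lines.append(",".join(f"{arr[i]:.9g}" for arr in arrays))
        path.write_text("\n".join(lines) + "\n", newline="\n")
        return path
    if format != "trc":
        raise ValueError(f"unknown reference format {format!r}")
    names = list(track.markers)
    name_row = "Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t"
    axis_row = "\t\t" + "\t".join(
        f"X{i+1}\tY{i+1}\tZ{i+1}" for i in range(len(names))
    )
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{track.fps:.9g}\t{track.fps:.9g}\t{n}\t{len(names)}\tm\t{track.fps:.9g}\t1\t{n}",
        name_row,
        axis_row,
        "",
    ]
    for i in range(n):
        fields = [str(i + 1), f"{i / track.fps:.9g}"]
        for name in names:
            fields += [f"{v:.9g}" for v in track.markers[name][i]]
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + "\n", newline="\n")
    return path


def align_time(
    a: np.ndarray,
    b: np.ndarray,
    max_lag: int,
) -> tuple[int, tuple[np.ndarray, np.ndarray], bool]:
    """Align two same-rate scalar series by normalized cross-correlation.

    Returns ``(lag, (a_aligned, b_aligned), at_boundary)`` where ``lag`` is
    the delay of ``b`` relative to ``a`` in samples (``b[i] ~ a[i - lag]``),
    maximizing the normalized cross-correlation over ``|lag| <= max_lag``;
    the aligned pair is the overlapping region after shifting ``b``.
    ``at_boundary`` warns that the best lag sits on the search edge.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if max_lag < 0:
        raise ValueError("max_lag must be >= 0")
    if min(len(a), len(b)) <= max_lag + 2:
        raise ValueError("series too short for the requested max_lag")
    best_lag, best_r = 0, -np.inf
    for lag in range(-max_lag, max_lag + 1):
        if lag >= 0:
            xa, xb = a[: len(a) - lag or None], b[lag:]
        else:
            xa, xb = a[-lag:], b[: len(b) + lag]
        m = min(len(xa), len(xb))
        xa, xb = xa[:m], xb[:m]
        sa, sb = xa.std(), xb.std()
        if sa == 0 or sb == 0:
            continue
        r = float(np.mean((xa - xa.mean()) * (xb - xb.mean())) / (sa * sb))
        if r > best_r:
            best_lag, best_r = lag, r
    at_boundary = abs(best_lag) == max_lag and max_lag > 0
    if at_boundary:
        warnings.warn(f"alignment lag {best_lag} hit the search boundary", stacklevel=2)
    lag = best_lag
    if lag >= 0:
        m = min(len(a) - lag, len(b) - lag)
        pair = (a[: m], b[lag : lag + m])
    else:
        m = min(len(a) + lag, len(b) + lag)
        pair = (a[-lag : -lag + m], b[:m])
    return lag, pair, at_boundary


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson requires two equal-length 1-D series")
    if len(x) < 3:
        raise UndefinedCorrelationError("need at least 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def comparison_table(
    tracked: Sequence[TrackingRecord],
    reference: ReferenceTrack,
    keypoints: Sequence[KeypointID] | None = None,
    use_smoothed: bool = True,
) -> pd.DataFrame:
    """Per-keypoint, per-axis means of both streams and their Pearson r.

    Streams are assumed time-aligned and equally sampled (use
    :func:`align_time` first).  Reference labels that do not name skeleton
    keypoints are skipped with a warning.  Columns: keypoint, axis,
    mean_tracked, mean_reference, r.
    """
    mapped = reference.mapped_keypoints()
    unmatched = set(reference.markers) - {k.name for k in mapped}
    for label in sorted(unmatched):
        warnings.warn(f"reference label {label!r} matches no keypoint; skipped", stacklevel=2)
    coords = np.stack([r.smoothed if use_smoothed else r.raw for r in tracked])
    n = min(coords.shape[0], reference.n_frames())
    rows = []
    for kp in keypoints or sorted(mapped):
        if kp not in mapped:
            warnings.warn(f"keypoint {KeypointID(kp).name} missing from reference; skipped",
                          stacklevel=2)
            continue
        ref = mapped[kp][:n]
        trk = coords[:n, int(kp), :]
        for ai, axis in enumerate(_AXES):
            rows.append(
                {
                    "keypoint": KeypointID(kp).name,
                    "axis": axis.upper(),
                    "mean_tracked": float(np.nanmean(trk[:, ai])),
                    "mean_reference": float(np.nanmean(ref[:, ai])),
                    "r": pearson(trk[:, ai], ref[:, ai]),
                }
            )
    return pd.DataFrame(rows)
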
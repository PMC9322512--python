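"""Volumetric heatmap + offset codec.

A normalized pose lives inside a cube centered on the navel.  Each keypoint is
encoded as a G x G x G occupancy grid (the 3D heatmap) plus three offset grids
holding, at the occupied cell, the within-cell displacement from the cell
center as a fraction of the half-cell in [-1, 1] — one bounded channel per
axis, the "RGB colors" of the volume.  Decoding selects the hottest cell
(disambiguated against the two previously decoded frames), then adds the fine
correction, recovering a continuous position from a coarse grid.

Grid convention: cell (0, 0, 0) sits at the (-,-,-) corner of the cube; arrays
are indexed ``[i, j, k]`` for (x, y, z); linear order for tie-breaking is
x-fastest (l = i + G*j + G*G*k).
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import softmax

from .skeleton import N_KEYPOINTS, KeypointID, Pose3D

__all__ = [
    "CubeSpec",
    "PoseVolumes",
    "OutOfCubeError",
    "InvalidHeatmapError",
    "encode",
    "decode",
    "hottest_cell",
    "candidate_cells",
    "temporal_match",
    "probability_normalize",
]


class OutOfCubeError(ValueError):
    """A keypoint lies outside the encoding cube."""


class InvalidHeatmapError(ValueError):
    """A heat grid contains no usable (finite, nonnegative) values."""


@dataclass(frozen=True)
class CubeSpec:
    """Geometry of the encoding cube: half side length and grid resolution."""

    half_side: float = 1.5
    grid_size: int = 28

    def __post_init__(self) -> None:
        if self.half_side <= 0:
            raise ValueError("half_side must be > 0")
        if self.grid_size < 2:
            raise ValueError("grid_size must be >= 2")

    @property
    def cell_size(self) -> float:
        return 2.0 * self.half_side / self.grid_size

    def cell_center(self, idx: Sequence[int]) -> np.ndarray:
        """World (body-relative) coordinates of a cell's center."""
        idx = np.asarray(idx, dtype=float)
        return -self.half_side + (idx + 0.5) * self.cell_size

    def point_to_cell(self, p: np.ndarray, name: str = "point") -> tuple[int, int, int]:
        """Containing cell of a point; the +half_side faces belong to the last cell."""
        p = np.asarray(p, dtype=float)
        h = self.half_side
        if not np.isfinite(p).all() or (np.abs(p) > h).any():
            raise OutOfCubeError(f"{name} at {p} is outside the cube (half side {h})")
        idx = np.floor((p + h) / self.cell_size).astype(int)
        idx = np.minimum(idx, self.grid_size - 1)  # p exactly on the + face
        return int(idx[0]), int(idx[1]), int(idx[2])

    def linear_index(self, idx: Sequence[int]) -> int:
        i, j, k = idx
        g = self.grid_size
        return int(i) + g * int(j) + g * g * int(k)


@dataclass
class PoseVolumes:
    """One heat grid and three offset grids per keypoint (24 volumes)."""

    heat: np.ndarray  # (24, G, G, G), nonnegative
    offsets: np.ndarray  # (24, 3, G, G, G), in [-1, 1]
    spec: CubeSpec = field(default_factory=CubeSpec)

    def __post_init__(self) -> None:
        g = self.spec.grid_size
        if self.heat.shape != (N_KEYPOINTS, g, g, g):
            raise ValueError(f"heat must have shape (24, {g}, {g}, {g})")
        if self.offsets.shape != (N_KEYPOINTS, 3, g, g, g):
            raise ValueError(f"offsets must have shape (24, 3, {g}, {g}, {g})")

    # -- flat binary serialization (runtime fixtures/checkpoints) -------------
    _MAGIC = b"GPV1"

    def to_bytes(self) -> bytes:
        head = struct.pack(
            "<4sIId", self._MAGIC, N_KEYPOINTS, self.spec.grid_size, self.spec.half_side
        )
        return (
            head
            + self.heat.astype("<f4").tobytes()
            + self.offsets.astype("<f4").tobytes()
        )

    @classmethod
    def from_bytes(cls, blob: bytes) -> "PoseVolumes":
        hsize = struct.calcsize("<4sIId")
        magic, nkp, g, half = struct.unpack("<4sIId", blob[:hsize])
        if magic != cls._MAGIC or nkp != N_KEYPOINTS:
            raise ValueError("not a pose-volume blob")
        nh = nkp * g * g * g
        body = np.frombuffer(blob, dtype="<f4", offset=hsize)
        heat = body[:nh].reshape(nkp, g, g, g).astype(float)
        offs = body[nh : nh + 3 * nh].reshape(nkp, 3, g, g, g).astype(float)
        return cls(heat, offs, CubeSpec(half, g))


def encode(
    pose: Pose3D,
    spec: CubeSpec = CubeSpec(),
    heat_shape: str = "one_hot",
    sigma: float | None = None,
) -> PoseVolumes:
    """Encode a normalized pose as per-keypoint heat + offset volumes.

    ``heat_shape`` is ``"one_hot"`` (the containing cell gets heat 1) or
    ``"gaussian"`` (a normalized isotropic bump of width ``sigma``
    body-relative units centered on the keypoint).  Offsets are written only
    at the containing cell, scaled so that [-1, 1] spans the half-cell.
    """
    g = spec.grid_size
    heat = np.zeros((N_KEYPOINTS, g, g, g))
    offsets = np.zeros((N_KEYPOINTS, 3, g, g, g))
    if heat_shape == "gaussian":
        if sigma is None or sigma <= 0:
            raise ValueError("gaussian heat_shape requires sigma > 0")
        ax = -spec.half_side + (np.arange(g) + 0.5) * spec.cell_size
    elif heat_shape != "one_hot":
        raise ValueError(f"unknown heat_shape {heat_shape!r}")

    for kp in KeypointID:
        p = pose[kp]
        i, j, k = spec.point_to_cell(p, name=kp.name)
        if heat_shape == "one_hot":
            heat[kp, i, j, k] = 1.0
        else:
            d2 = (
                (ax[:, None, None] - p[0]) ** 2
                + (ax[None, :, None] - p[1]) ** 2
                + (ax[None, None, :] - p[2]) ** 2
            )
            bump = np.exp(-0.5 * d2 / sigma**2)
            heat[kp] = bump / bump.sum()
        offsets[kp, :, i, j, k] = (p - spec.cell_center((i, j, k))) / (spec.cell_size / 2)
    return PoseVolumes(heat, offsets, spec)


def _check_heat(heat: np.ndarray) -> np.ndarray:
    heat = np.asarray(heat, dtype=float)
    if not np.isfinite(heat).any():
        raise InvalidHeatmapError("heat grid has no finite values")
    return heat


def hottest_cell(heat: np.ndarray) -> tuple[int, int, int]:
    """Argmax cell of a heat grid; ties broken by smallest x-fastest linear index."""
    heat = _check_heat(heat)
    g = heat.shape[0]
    # transpose to (z, y, x) so C-order ravel enumerates x fastest
    flat = np.where(np.isfinite(heat), heat, -np.inf).transpose(2, 1, 0).reshape(-1)
    l = int(np.argmax(flat))
    return l % g, (l // g) % g, l // (g * g)


def probability_normalize(heat: np.ndarray) -> np.ndarray:
    """Softmax over all cells of a raw-score grid: positive, sums to 1."""
    heat = np.asarray(heat, dtype=float)
    return softmax(heat.reshape(-1)).reshape(heat.shape)


def candidate_cells(
    heat: np.ndarray, eps: float = 0.05
) -> list[tuple[int, int, int]]:
    """Cells within ``eps`` (relative) of the maximum heat, in linear order."""
    heat = _check_heat(heat)
    g = heat.shape[0]
    finite = np.where(np.isfinite(heat), heat, -np.inf)
    mx = finite.max()
    ii, jj, kk = np.nonzero(finite >= mx - eps * abs(mx) - (0.0 if mx != 0 else eps))
    cells = sorted(zip(ii, jj, kk), key=lambda c: c[0] + g * c[1] + g * g * c[2])
    return [(int(i), int(j), int(k)) for i, j, k in cells]


def temporal_match(
    candidates: Sequence[tuple[int, int, int]],
    prev1: np.ndarray | None,
    prev2: np.ndarray | None,
    spec: CubeSpec = CubeSpec(),
    heats: Sequence[float] | None = None,
    sigma: float = 0.5,
) -> tuple[int, int, int]:
    """Pick among near-maximal heat cells using the previous two positions.

    The expected position is the linear extrapolation ``2*prev1 - prev2`` of
    the two previously decoded frames (or ``prev1`` with one frame of
    history).  When per-candidate ``heats`` are supplied, candidates are
    scored by ``log(heat) - d^2 / (2*sigma^2)`` — heat evidence balanced
    against motion continuity, with ``sigma`` the expected per-frame motion
    scale in body-relative units; without ``heats``, the nearest candidate
    wins (so equal-heat ties resolve purely by proximity).  Without history
    the maximum heat (or, lacking that, the smallest x-fastest linear index)
    is returned.  All ties break to the smallest linear index, and the
    selection never leaves the candidate set.
    """
    if len(candidates) == 0:
        raise ValueError("temporal_match requires at least one candidate")
    if len(candidates) == 1:
        return tuple(candidates[0])
    if heats is not None and len(heats) != len(candidates):
        raise ValueError("heats must align with candidates")

    if heats is None:
        scores = np.zeros(len(candidates))
    else:
        scores = np.log(np.maximum(np.asarray(heats, dtype=float), 1e-300))
    if prev1 is None:
        if heats is None:
            return min(candidates, key=spec.linear_index)
    else:
        target = np.asarray(prev1, dtype=float)
        if prev2 is not None:
            target = 2.0 * target - np.asarray(prev2, dtype=float)
        d2 = np.array(
            [float(np.sum((spec.cell_center(c) - target) ** 2)) for c in candidates]
        )
        scores = scores - d2 / (2.0 * sigma**2)
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-scores[i], spec.linear_index(candidates[i])),
    )
    return tuple(candidates[order[0]])


def decode(
    volumes: PoseVolumes,
    spec: CubeSpec | None = None,
    history: Sequence[Pose3D] = (),
    eps: float = 0.2,
    sigma: float = 0.5,
    frame_index: int = 0,
    timestamp: float = 0.0,
) -> tuple[Pose3D, np.ndarray]:
    """Decode volumes back to a pose and per-keypoint confidences.

    Per keypoint the heat grid is normalized to probabilities (divide by the
    sum) and a cell is chosen among those within ``eps`` (relative) of the
    maximum: without history, the hottest; with up to two previous poses
    (most recent first), the :func:`temporal_match` blend of heat evidence
    and motion continuity, which resolves the left/right and depth
    ambiguities that plague single-frame monocular decoding.  The coordinate
    is the cell center plus ``offset * cell_size/2``; the confidence is the
    maximum normalized heat — 1 for a one-hot grid, ``1/G^3`` for a uniform
    one.
    """
    spec = spec or volumes.spec
    coords = np.zeros((N_KEYPOINTS, 3))
    conf = np.zeros(N_KEYPOINTS)
    prev1 = history[0] if len(history) >= 1 else None
    prev2 = history[1] if len(history) >= 2 else None
    for kp in KeypointID:
        heat = _check_heat(volumes.heat[kp])
        if (heat < 0).any():
            raise InvalidHeatmapError(f"negative heat for {kp.name}")
        total = float(np.nansum(heat))
        if total <= 0 or not np.isfinite(total):
            raise InvalidHeatmapError(f"heat for {kp.name} does not sum to a positive value")
        prob = np.where(np.isfinite(heat), heat, 0.0) / total
        cands = candidate_cells(prob, eps=eps)
        cell = temporal_match(
            cands,
            None if prev1 is None else prev1[kp],
            None if prev2 is None else prev2[kp],
            spec,
            heats=[float(prob[c]) for c in cands],
            sigma=sigma,
        )
        off = volumes.offsets[(kp, slice(None)) + cell]
        coords[kp] = spec.cell_center(cell) + off * (spec.cell_size / 2.0)
        conf[kp] = float(prob[cell])
    return Pose3D(coords, frame_index, timestamp), conf
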
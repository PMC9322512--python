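"""Canonical 24-keypoint skeleton, body-relative normalization and joint-angle geometry.

The skeleton is the fixed set of 24 anatomical landmarks tracked by the
pipeline, with the navel (body center) first.  All downstream stages work in
*body-relative* coordinates: the navel sits at the origin, the upper body is
scaled so the navel-to-head-center distance is 1, and the lower body is scaled
so the navel-to-ankle distance is 1.  There is no ground reference.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Literal

import numpy as np

__all__ = [
    "KeypointID",
    "Pose3D",
    "MotionSequence",
    "JointAngles",
    "InvalidPoseError",
    "DegeneratePoseError",
    "UPPER_KEYPOINTS",
    "LOWER_KEYPOINTS",
    "head_center",
    "neck_point",
    "normalize_pose",
    "normalize_sequence",
    "vector_angle",
    "limb_angles",
    "JOINT_KEYPOINTS",
]


class KeypointID(enum.IntEnum):
    """The 24 tracked landmarks; the navel (body center) has index 0."""

    navel = 0
    nose = 1
    ear_l = 2
    ear_r = 3
    eye_l = 4
    eye_r = 5
    shoulder_l = 6
    shoulder_r = 7
    elbow_l = 8
    elbow_r = 9
    wrist_l = 10
    wrist_r = 11
    thumb_l = 12
    thumb_r = 13
    middle_finger_l = 14
    middle_finger_r = 15
    hip_l = 16
    hip_r = 17
    knee_l = 18
    knee_r = 19
    ankle_l = 20
    ankle_r = 21
    toe_l = 22
    toe_r = 23


N_KEYPOINTS = len(KeypointID)

#: Keypoints scaled by the upper-body factor (navel -> head-center distance = 1).
UPPER_KEYPOINTS: frozenset[KeypointID] = frozenset(
    {
        KeypointID.nose,
        KeypointID.ear_l,
        KeypointID.ear_r,
        KeypointID.eye_l,
        KeypointID.eye_r,
        KeypointID.shoulder_l,
        KeypointID.shoulder_r,
        KeypointID.elbow_l,
        KeypointID.elbow_r,
        KeypointID.wrist_l,
        KeypointID.wrist_r,
        KeypointID.thumb_l,
        KeypointID.thumb_r,
        KeypointID.middle_finger_l,
        KeypointID.middle_finger_r,
    }
)

#: Keypoints scaled by the lower-body factor (navel -> ankle distance = 1).
LOWER_KEYPOINTS: frozenset[KeypointID] = frozenset(
    {
        KeypointID.hip_l,
        KeypointID.hip_r,
        KeypointID.knee_l,
        KeypointID.knee_r,
        KeypointID.ankle_l,
        KeypointID.ankle_r,
        KeypointID.toe_l,
        KeypointID.toe_r,
    }
)


class InvalidPoseError(ValueError):
    """A pose contains non-finite coordinates where finite ones are required."""


class DegeneratePoseError(ValueError):
    """A reference segment (navel->head or navel->ankle) has zero length."""


@dataclass
class Pose3D:
    """One frame's 24 keypoint positions.

    ``coords`` is a (24, 3) float array; units are arbitrary world units
    before :func:`normalize_pose` and body-relative units after.
    """

    coords: np.ndarray
    frame_index: int = 0
    timestamp: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (N_KEYPOINTS, 3):
            raise InvalidPoseError(
                f"pose coords must have shape (24, 3), got {self.coords.shape}"
            )
        if self.frame_index < 0:
            raise InvalidPoseError("frame_index must be >= 0")

    def __getitem__(self, key: KeypointID | int) -> np.ndarray:
        return self.coords[int(key)]

    def copy(self) -> "Pose3D":
        return Pose3D(self.coords.copy(), self.frame_index, self.timestamp)


@dataclass
class MotionSequence:
    """An ordered run of poses sampled at a constant frame rate."""

    frames: list[Pose3D]
    fps: float

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        idx = [f.frame_index for f in self.frames]
        if idx and idx != list(range(idx[0], idx[0] + len(idx))):
            raise ValueError("frame_index must increase by exactly 1")

    def __len__(self) -> int:
        return len(self.frames)

    def as_array(self) -> np.ndarray:
        """Stack coordinates into an (n_frames, 24, 3) array."""
        return np.stack([f.coords for f in self.frames], axis=0)


@dataclass
class JointAngles:
    """Per-frame 3D joint angles, in degrees, each within [0, 180]."""

    neck: float
    lumbar: float
    hip_l: float
    hip_r: float
    knee_l: float
    knee_r: float
    ankle_l: float
    ankle_r: float

    JOINTS = ("neck", "lumbar", "hip_l", "hip_r", "knee_l", "knee_r", "ankle_l", "ankle_r")

    def as_dict(self) -> dict[str, float]:
        return {j: getattr(self, j) for j in self.JOINTS}


def _midpoint(pose: Pose3D, a: KeypointID, b: KeypointID, what: str) -> np.ndarray:
    pa, pb = pose[a], pose[b]
    if not (np.isfinite(pa).all() and np.isfinite(pb).all()):
        raise InvalidPoseError(f"non-finite {what} coordinates")
    return 0.5 * (pa + pb)


def head_center(pose: Pose3D) -> np.ndarray:
    """Center of the head: the midpoint of both ears."""
    return _midpoint(pose, KeypointID.ear_l, KeypointID.ear_r, "ear")


def neck_point(pose: Pose3D) -> np.ndarray:
    """The neck: the midpoint of both shoulders."""
    return _midpoint(pose, KeypointID.shoulder_l, KeypointID.shoulder_r, "shoulder")


AnkleRule = Literal["mean", "left", "right"]


def _reference_lengths(pose: Pose3D, ankle_rule: AnkleRule) -> tuple[np.ndarray, float, float]:
    """Navel position and the two reference distances of a world pose."""
    navel = pose[KeypointID.navel]
    if not np.isfinite(navel).all():
        raise InvalidPoseError("non-finite navel coordinates")
    upper_len = float(np.linalg.norm(head_center(pose) - navel))
    d_l = float(np.linalg.norm(pose[KeypointID.ankle_l] - navel))
    d_r = float(np.linalg.norm(pose[KeypointID.ankle_r] - navel))
    if ankle_rule == "left":
        lower_len = d_l
    elif ankle_rule == "right":
        lower_len = d_r
    elif ankle_rule == "mean":
        lower_len = 0.5 * (d_l + d_r)
    else:
        raise ValueError(f"unknown ankle_rule {ankle_rule!r}")
    if not np.isfinite(lower_len):
        raise InvalidPoseError("non-finite ankle coordinates")
    if upper_len <= 0.0 or lower_len <= 0.0:
        raise DegeneratePoseError(
            "zero-length reference segment (navel->head or navel->ankle)"
        )
    return navel, upper_len, lower_len


def _apply_normalization(
    pose: Pose3D, navel: np.ndarray, upper_len: float, lower_len: float
) -> Pose3D:
    coords = pose.coords - navel
    out = coords.copy()
    for kp in UPPER_KEYPOINTS:
        out[int(kp)] = coords[int(kp)] / upper_len
    for kp in LOWER_KEYPOINTS:
        out[int(kp)] = coords[int(kp)] / lower_len
    out[int(KeypointID.navel)] = 0.0
    return Pose3D(out, pose.frame_index, pose.timestamp)


def normalize_pose(pose: Pose3D, ankle_rule: AnkleRule = "mean") -> Pose3D:
    """Convert a world pose to body-relative coordinates.

    The navel is translated to the origin.  The upper body (nose, ears, eyes,
    shoulders, arms, hands) is scaled so the navel-to-head-center distance is
    1; the lower body (hips and below) is scaled so the navel-to-ankle
    distance is 1, where ``ankle_rule`` selects the left ankle, the right
    ankle, or (default) the mean of both distances.  The operation is
    idempotent.
    """
    navel, upper_len, lower_len = _reference_lengths(pose, ankle_rule)
    return _apply_normalization(pose, navel, upper_len, lower_len)


def normalize_sequence(
    seq: MotionSequence,
    mode: Literal["per_frame", "per_sequence"] = "per_frame",
    ankle_rule: AnkleRule = "mean",
) -> MotionSequence:
    """Normalize every frame of a sequence.

    ``per_frame`` (default) recomputes the translation and both scale factors
    on each frame, matching per-image network targets.  ``per_sequence``
    freezes the scale factors from the first frame (translation still per
    frame), which preserves apparent limb-length changes across the sequence.
    """
    if mode == "per_frame":
        frames = [normalize_pose(f, ankle_rule) for f in seq.frames]
    elif mode == "per_sequence":
        _, upper_len, lower_len = _reference_lengths(seq.frames[0], ankle_rule)
        frames = [
            _apply_normalization(f, f[KeypointID.navel], upper_len, lower_len)
            for f in seq.frames
        ]
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return MotionSequence(frames, seq.fps)


def vector_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two 3-vectors in degrees, in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0 or not (np.isfinite(nu) and np.isfinite(nv)):
        raise DegeneratePoseError("vector_angle requires two nonzero finite vectors")
    # atan2 of (|u x v|, u.v) stays well-conditioned near 0 and 180 degrees,
    # where the arccos form loses ~7 digits
    cross = np.linalg.norm(np.cross(u, v))
    return float(np.degrees(np.arctan2(cross, np.dot(u, v))))


#: Keypoints whose confidence scores determine each joint angle's reliability.
JOINT_KEYPOINTS: dict[str, tuple[KeypointID, ...]] = {
    "neck": (
        KeypointID.shoulder_l,
        KeypointID.shoulder_r,
        KeypointID.ear_l,
        KeypointID.ear_r,
        KeypointID.navel,
    ),
    "lumbar": (
        KeypointID.navel,
        KeypointID.shoulder_l,
        KeypointID.shoulder_r,
        KeypointID.hip_l,
        KeypointID.hip_r,
    ),
    "hip_l": (KeypointID.navel, KeypointID.hip_l, KeypointID.knee_l),
    "hip_r": (KeypointID.navel, KeypointID.hip_r, KeypointID.knee_r),
    "knee_l": (KeypointID.hip_l, KeypointID.knee_l, KeypointID.ankle_l),
    "knee_r": (KeypointID.hip_r, KeypointID.knee_r, KeypointID.ankle_r),
    "ankle_l": (KeypointID.knee_l, KeypointID.ankle_l, KeypointID.toe_l),
    "ankle_r": (KeypointID.knee_r, KeypointID.ankle_r, KeypointID.toe_r),
}

AngleConvention = Literal["vector", "flexion"]


def limb_angles(pose: Pose3D, convention: AngleConvention = "flexion") -> JointAngles:
    """3D joint angles of the neck, lumbar and bilateral hip/knee/ankle.

    Each joint angle is the angle between the two limb vectors meeting at the
    joint: knee = (knee->hip, knee->ankle); hip = (hip->navel, hip->knee);
    ankle = (ankle->knee, ankle->toe); neck = (neck->head-center,
    neck->navel); lumbar = (navel->neck, navel->hip-midpoint).  Under the
    default ``flexion`` convention each reported value is 180 degrees minus
    the vector angle, so a fully extended (collinear) limb reads 0.

    The neck and lumbar definitions are this package's own convention; the
    hip/knee/ankle definitions follow standard vector-angle gait practice.
    """
    K = KeypointID
    navel = pose[K.navel]
    hc = head_center(pose)
    neck = neck_point(pose)
    hip_mid = 0.5 * (pose[K.hip_l] + pose[K.hip_r])

    def ang(a: np.ndarray, b: np.ndarray) -> float:
        raw = vector_angle(a, b)
        return 180.0 - raw if convention == "flexion" else raw

    if convention not in ("vector", "flexion"):
        raise ValueError(f"unknown angle convention {convention!r}")

    out: dict[str, float] = {
        "neck": ang(hc - neck, navel - neck),
        "lumbar": ang(neck - navel, hip_mid - navel),
    }
    for side in ("l", "r"):
        hip = pose[K[f"hip_{side}"]]
        knee = pose[K[f"knee_{side}"]]
        ankle = pose[K[f"ankle_{side}"]]
        toe = pose[K[f"toe_{side}"]]
        out[f"hip_{side}"] = ang(navel - hip, knee - hip)
        out[f"knee_{side}"] = ang(hip - knee, ankle - knee)
        out[f"ankle_{side}"] = ang(knee - ankle, toe - ankle)
    return JointAngles(**out)
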
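"""Synthetic articulated characters, procedural motions and a square-frame renderer.

This module stands in for a motion-capture studio: it builds parametric
stick-figure characters with randomized segment lengths, drives them through
procedural motions (walking a circle, rotating in place with arms out, and
smooth random "dance"), and renders square RGB frames with a pinhole camera
whose optical axis always passes through the body center.  Each rendered
frame is paired with the ground-truth 24-keypoint pose, so image/pose
training pairs can be produced in any quantity with no external data.

World frame: y is up, characters move in the x–z ground plane.  Heading yaw
is measured about +y, with yaw 0 facing +z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from PIL import Image
from scipy.signal import butter, filtfilt

from .skeleton import (
    KeypointID,
    MotionSequence,
    N_KEYPOINTS,
    Pose3D,
    normalize_sequence,
)

__all__ = [
    "BodyModel",
    "MotionScript",
    "RenderSettings",
    "TrainingSample",
    "OutOfFrameError",
    "make_character",
    "generate_motion",
    "generate_walk",
    "generate_rotation",
    "generate_dance",
    "project_keypoints",
    "render_frame",
    "build_dataset",
    "load_manifest",
    "BONES",
]

K = KeypointID

#: Template segment lengths in meters (rough adult proportions).
_TEMPLATE = {
    "torso": 0.32,          # navel -> neck
    "neck_to_head": 0.22,   # neck -> head center (ear midpoint)
    "shoulder_width": 0.38,
    "upper_arm": 0.30,
    "lower_arm": 0.27,
    "hand": 0.18,
    "pelvis_width": 0.30,
    "navel_to_pelvis": 0.14,  # navel -> hip line (vertical drop)
    "thigh": 0.45,
    "shank": 0.43,
    "foot": 0.22,
    "ear_offset": 0.09,
    "face_depth": 0.10,
}


@dataclass(frozen=True)
class BodyModel:
    """A parametric stick-figure character, deterministic in its seed."""

    torso: float
    neck_to_head: float
    shoulder_width: float
    upper_arm: float
    lower_arm: float
    hand: float
    pelvis_width: float
    navel_to_pelvis: float
    thigh: float
    shank: float
    foot: float
    ear_offset: float
    face_depth: float
    limb_thickness: float = 14.0  # pixels at the reference render size (448)
    limb_colors: tuple[tuple[int, int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in _TEMPLATE:
            if getattr(self, name) <= 0:
                raise ValueError(f"segment length {name} must be > 0")

    @property
    def navel_height(self) -> float:
        """Standing navel height: pelvis drop plus a straight leg."""
        return self.navel_to_pelvis + self.thigh + self.shank


def make_character(seed: int, variation: float = 0.08) -> BodyModel:
    """Draw a character whose segment lengths vary around the template.

    ``variation`` is the relative half-width of the uniform spread on every
    segment; 0 reproduces the template exactly.  Same seed, same character.
    """
    if seed < 0:
        raise ValueError("seed must be >= 0")
    rng = np.random.default_rng(seed)
    lengths = {
        name: base * (1.0 + variation * float(rng.uniform(-1.0, 1.0)))
        for name, base in _TEMPLATE.items()
    }
    # one color per limb group (trunk, head, arms, legs), hues evenly spaced
    # around the wheel so no two limbs alias visually
    import colorsys

    hue0 = float(rng.uniform(0, 1))
    colors = tuple(
        tuple(
            int(round(255 * c))
            for c in colorsys.hsv_to_rgb(
                (hue0 + i / 6.0) % 1.0,
                float(rng.uniform(0.7, 1.0)),
                float(rng.uniform(0.7, 1.0)),
            )
        )
        for i in range(6)
    )
    return BodyModel(**lengths, limb_thickness=14.0, limb_colors=colors, seed=seed)


MotionKind = Literal["circle_walk", "rotation_in_place", "dance"]


@dataclass(frozen=True)
class MotionScript:
    """Parameters of one procedural motion clip."""

    kind: MotionKind = "circle_walk"
    duration: float = 10.0  # seconds
    fps: float = 30.0
    # gait parameters
    cadence: float = 1.8  # steps per second (one gait cycle = 2 steps)
    hip_amplitude: float = 25.0  # degrees
    knee_amplitude: float = 40.0  # degrees; gait knee flexion spans 0..40
    ankle_amplitude: float = 10.0  # degrees
    arm_swing_amplitude: float = 20.0  # degrees
    knee_phase: float = math.pi / 3  # knee lags hip within the cycle
    # circle path
    diameter: float = 1.0  # meters
    direction: Literal["cw", "ccw"] = "ccw"
    laps: float = 2.0
    # rotation in place
    turn_rate: float = 36.0  # degrees per second
    arm_abduction: float = 90.0  # degrees, arms extended sideways
    # dance
    smoothness: float = 1.5  # low-pass cutoff of the random joint drive, Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fps <= 60):
            raise ValueError("fps must be in (0, 60]")
        if self.kind == "circle_walk" and self.diameter <= 0:
            raise ValueError("circle_walk requires diameter > 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.fps))


def _frame_axes(yaw: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(forward, left, up) unit vectors for a heading yaw about +y."""
    forward = np.array([math.sin(yaw), 0.0, math.cos(yaw)])
    left = np.array([math.cos(yaw), 0.0, -math.sin(yaw)])
    up = np.array([0.0, 1.0, 0.0])
    return forward, left, up


def _pose_from_state(
    body: BodyModel,
    navel: np.ndarray,
    yaw: float,
    joints: dict[str, float],
) -> np.ndarray:
    """Forward kinematics: place all 24 keypoints from joint angles (degrees).

    Joint channels (all default 0 = neutral standing): ``hip_l/r`` thigh
    pitch forward, ``knee_l/r`` knee flexion (>= 0 bends backward),
    ``ankle_l/r`` foot pitch (dorsiflexion positive), ``arm_pitch_l/r``
    shoulder swing forward, ``arm_abduction_l/r`` arm lift sideways,
    ``elbow_l/r`` elbow flexion.
    """
    fwd, left, up = _frame_axes(yaw)
    j = {k: math.radians(v) for k, v in joints.items()}
    g = lambda name: j.get(name, 0.0)

    c = np.zeros((N_KEYPOINTS, 3))
    c[K.navel] = navel
    neck = navel + up * body.torso
    head = neck + up * body.neck_to_head
    c[K.ear_l] = head + left * body.ear_offset
    c[K.ear_r] = head - left * body.ear_offset
    c[K.eye_l] = head + fwd * body.face_depth * 0.8 + left * 0.035 + up * 0.02
    c[K.eye_r] = head + fwd * body.face_depth * 0.8 - left * 0.035 + up * 0.02
    c[K.nose] = head + fwd * body.face_depth - up * 0.02
    c[K.shoulder_l] = neck + left * (body.shoulder_width / 2)
    c[K.shoulder_r] = neck - left * (body.shoulder_width / 2)

    pelvis = navel - up * body.navel_to_pelvis
    c[K.hip_l] = pelvis + left * (body.pelvis_width / 2)
    c[K.hip_r] = pelvis - left * (body.pelvis_width / 2)

    for side, sgn in (("l", 1.0), ("r", -1.0)):
        lat = left * sgn  # outward lateral direction for this side
        # ---- leg chain -----------------------------------------------------
        hip_a = g(f"hip_{side}")
        knee_a = g(f"knee_{side}")
        thigh_dir = -up * math.cos(hip_a) + fwd * math.sin(hip_a)
        knee = c[K[f"hip_{side}"]] + body.thigh * thigh_dir
        shank_pitch = hip_a - knee_a  # knee flexion folds the shank backward
        shank_dir = -up * math.cos(shank_pitch) + fwd * math.sin(shank_pitch)
        ankle = knee + body.shank * shank_dir
        foot_pitch = g(f"ankle_{side}")
        toe = ankle + body.foot * (fwd * math.cos(foot_pitch) + up * math.sin(foot_pitch))
        c[K[f"knee_{side}"]] = knee
        c[K[f"ankle_{side}"]] = ankle
        c[K[f"toe_{side}"]] = toe
        # ---- arm chain -----------------------------------------------------
        ab = g(f"arm_abduction_{side}")
        sw = g(f"arm_pitch_{side}")
        hang = -up * math.cos(ab) + lat * math.sin(ab)
        ua_dir = hang * math.cos(sw) + fwd * math.sin(sw)
        elbow = c[K[f"shoulder_{side}"]] + body.upper_arm * ua_dir
        el = g(f"elbow_{side}")
        fa_dir = ua_dir * math.cos(el) + fwd * math.sin(el)
        fa_dir = fa_dir / np.linalg.norm(fa_dir)
        wrist = elbow + body.lower_arm * fa_dir
        c[K[f"elbow_{side}"]] = elbow
        c[K[f"wrist_{side}"]] = wrist
        c[K[f"middle_finger_{side}"]] = wrist + body.hand * fa_dir
        thumb_dir = fa_dir + 0.8 * fwd
        thumb_dir = thumb_dir / np.linalg.norm(thumb_dir)
        c[K[f"thumb_{side}"]] = wrist + 0.55 * body.hand * thumb_dir
    return c


def _gait_joints(script: MotionScript, phase: float) -> dict[str, float]:
    """Joint angles of a symmetric gait at cycle phase ``phase`` (radians)."""
    s = script
    out: dict[str, float] = {}
    for side, ph in (("l", 0.0), ("r", math.pi)):
        p = phase + ph
        out[f"hip_{side}"] = s.hip_amplitude * math.sin(p)
        out[f"knee_{side}"] = s.knee_amplitude * 0.5 * (1.0 - math.cos(p - s.knee_phase))
        out[f"ankle_{side}"] = s.ankle_amplitude * math.sin(p + math.pi / 4)
        out[f"arm_pitch_{side}"] = s.arm_swing_amplitude * math.sin(p + math.pi)
        out[f"elbow_{side}"] = 15.0
    return out


def generate_walk(body: BodyModel, script: MotionScript) -> MotionSequence:
    """Walk around a circle: default 1 m diameter, two laps.

    The pelvis (navel) follows the circle at constant angular speed, the
    heading stays tangent to the path, and hip/knee/ankle flexion follow
    sinusoids with the scripted amplitudes, the two sides half a gait cycle
    apart.  The cumulative heading change is ``laps * 360`` degrees.
    """
    if script.kind != "circle_walk":
        raise ValueError(f"generate_walk cannot handle kind {script.kind!r}")
    r = script.diameter / 2.0
    sgn = 1.0 if script.direction == "ccw" else -1.0
    omega = sgn * 2.0 * math.pi * script.laps / script.duration
    cycle_rate = 2.0 * math.pi * script.cadence / 2.0  # gait cycles per second
    frames = []
    for i in range(script.n_frames):
        t = i / script.fps
        theta = omega * t
        navel = np.array(
            [r * math.cos(theta), body.navel_height - 0.015 * (1 - math.cos(2 * cycle_rate * t)), r * math.sin(theta)]
        )
        # tangent direction of the circle: d/dtheta (cos, sin) = (-sin, cos)
        yaw = math.atan2(-math.sin(theta) * sgn, math.cos(theta) * sgn)
        joints = _gait_joints(script, cycle_rate * t)
        coords = _pose_from_state(body, navel, yaw, joints)
        frames.append(Pose3D(coords, frame_index=i, timestamp=t))
    return MotionSequence(frames, script.fps)


def generate_rotation(body: BodyModel, script: MotionScript) -> MotionSequence:
    """Turn slowly in place with the upper limbs extended sideways."""
    if script.kind != "rotation_in_place":
        raise ValueError(f"generate_rotation cannot handle kind {script.kind!r}")
    navel = np.array([0.0, body.navel_height, 0.0])
    frames = []
    for i in range(script.n_frames):
        t = i / script.fps
        yaw = math.radians(script.turn_rate) * t
        joints = {
            "arm_abduction_l": script.arm_abduction,
            "arm_abduction_r": script.arm_abduction,
        }
        coords = _pose_from_state(body, navel, yaw, joints)
        frames.append(Pose3D(coords, frame_index=i, timestamp=t))
    return MotionSequence(frames, script.fps)


_DANCE_CHANNELS = (
    ("hip_l", 30.0), ("hip_r", 30.0), ("knee_l", 50.0), ("knee_r", 50.0),
    ("ankle_l", 15.0), ("ankle_r", 15.0), ("arm_pitch_l", 60.0), ("arm_pitch_r", 60.0),
    ("arm_abduction_l", 70.0), ("arm_abduction_r", 70.0), ("elbow_l", 70.0), ("elbow_r", 70.0),
)


def generate_dance(body: BodyModel, script: MotionScript) -> MotionSequence:
    """Smooth band-limited random whole-body movement (training diversity).

    Every joint channel is white noise low-pass filtered at
    ``script.smoothness`` Hz (zero-phase), scaled to a per-joint amplitude
    limit; knee channels are folded to stay nonnegative.  Deterministic in
    ``script.seed``.
    """
    if script.kind != "dance":
        raise ValueError(f"generate_dance cannot handle kind {script.kind!r}")
    rng = np.random.default_rng(script.seed)
    n = script.n_frames
    if script.smoothness >= script.fps / 2:
        raise ValueError("smoothness cutoff must be below the Nyquist frequency")
    b, a = butter(2, script.smoothness / (script.fps / 2.0))
    series: dict[str, np.ndarray] = {}
    for name, limit in _DANCE_CHANNELS:
        raw = rng.standard_normal(n + 120)
        smooth = filtfilt(b, a, raw)[60 : 60 + n]
        peak = np.abs(smooth).max() or 1.0
        vals = smooth / peak * limit
        if name.startswith("knee"):
            vals = np.abs(vals)
        series[name] = vals
    yaw_drive = filtfilt(b, a, rng.standard_normal(n + 120))[60 : 60 + n]
    yaw = np.cumsum(yaw_drive) / script.fps
    yaw = yaw / (np.abs(yaw).max() or 1.0) * math.pi

    navel = np.array([0.0, body.navel_height, 0.0])
    frames = []
    for i in range(n):
        joints = {name: float(series[name][i]) for name, _ in _DANCE_CHANNELS}
        coords = _pose_from_state(body, navel, float(yaw[i]), joints)
        frames.append(Pose3D(coords, frame_index=i, timestamp=i / script.fps))
    return MotionSequence(frames, script.fps)


_GENERATORS = {
    "circle_walk": generate_walk,
    "rotation_in_place": generate_rotation,
    "dance": generate_dance,
}


def generate_motion(body: BodyModel, script: MotionScript) -> MotionSequence:
    """Dispatch to the generator for ``script.kind``."""
    try:
        gen = _GENERATORS[script.kind]
    except KeyError:
        raise ValueError(f"unsupported motion kind {script.kind!r}") from None
    return gen(body, script)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


class OutOfFrameError(ValueError):
    """Part of the body projects outside the video frame."""


@dataclass(frozen=True)
class RenderSettings:
    """Square-frame pinhole camera with the body center on the optical axis."""

    image_side: int = 448
    camera_distance: float = 3.0  # meters from the navel along the optical axis
    focal_scale: float = 1.1  # focal length in units of image side
    background: Literal["plain", "noise"] = "plain"
    background_level: int = 32
    projection: Literal["perspective", "orthographic"] = "perspective"

    def __post_init__(self) -> None:
        if self.image_side < 64 or self.image_side % 2:
            raise ValueError("image_side must be >= 64 and even")
        if self.camera_distance <= 0:
            raise ValueError("camera_distance must be > 0")


#: Bones drawn by the renderer, with a color-group index per bone.
BONES: tuple[tuple[KeypointID, KeypointID, int], ...] = (
    (K.navel, K.shoulder_l, 0), (K.navel, K.shoulder_r, 0),
    (K.shoulder_l, K.shoulder_r, 0),
    (K.navel, K.hip_l, 0), (K.navel, K.hip_r, 0), (K.hip_l, K.hip_r, 0),
    (K.ear_l, K.ear_r, 1), (K.ear_l, K.nose, 1), (K.ear_r, K.nose, 1),
    (K.eye_l, K.nose, 1), (K.eye_r, K.nose, 1),
    (K.shoulder_l, K.elbow_l, 2), (K.elbow_l, K.wrist_l, 2),
    (K.wrist_l, K.thumb_l, 2), (K.wrist_l, K.middle_finger_l, 2),
    (K.shoulder_r, K.elbow_r, 3), (K.elbow_r, K.wrist_r, 3),
    (K.wrist_r, K.thumb_r, 3), (K.wrist_r, K.middle_finger_r, 3),
    (K.hip_l, K.knee_l, 4), (K.knee_l, K.ankle_l, 4), (K.ankle_l, K.toe_l, 4),
    (K.hip_r, K.knee_r, 5), (K.knee_r, K.ankle_r, 5), (K.ankle_r, K.toe_r, 5),
)


def project_keypoints(
    pose: Pose3D, settings: RenderSettings = RenderSettings()
) -> np.ndarray:
    """Project world keypoints to pixel coordinates (column, row).

    The camera sits ``camera_distance`` meters from the navel along world -z
    (so the body center is always on the optical axis), with +x to the image
    right and +y up (image rows grow downward).
    """
    navel = pose[K.navel]
    rel = pose.coords - navel  # camera tracks the body center
    s = settings.image_side
    f = settings.focal_scale * s
    if settings.projection == "perspective":
        z = settings.camera_distance + rel[:, 2]
        if (z <= 1e-6).any():
            raise OutOfFrameError("keypoint at or behind the camera plane")
        u = s / 2.0 + f * rel[:, 0] / z
        v = s / 2.0 - f * rel[:, 1] / z
    else:
        scale = f / settings.camera_distance
        u = s / 2.0 + scale * rel[:, 0]
        v = s / 2.0 - scale * rel[:, 1]
    return np.stack([u, v], axis=1)


def _background(settings: RenderSettings, rng_seed: int | None) -> np.ndarray:
    s = settings.image_side
    if settings.background == "plain":
        return np.full((s, s, 3), float(settings.background_level))
    rng = np.random.default_rng(0 if rng_seed is None else rng_seed)
    return rng.uniform(0, 2 * settings.background_level, size=(s, s, 3))


def render_frame(
    pose: Pose3D,
    body: BodyModel,
    settings: RenderSettings = RenderSettings(),
    background_seed: int | None = None,
) -> np.ndarray:
    """Render one square RGB frame (uint8, side x side x 3) of a world pose.

    Limbs are drawn as anti-aliased thick segments between projected
    keypoints.  Raises :class:`OutOfFrameError` when any keypoint leaves the
    frame, mirroring the unreliable-capture condition of a real recording.
    """
    px = project_keypoints(pose, settings)
    s = settings.image_side
    if (px < 0).any() or (px >= s).any():
        bad = [K(i).name for i in np.nonzero(((px < 0) | (px >= s)).any(axis=1))[0]]
        raise OutOfFrameError(f"keypoints out of frame: {', '.join(bad)}")

    canvas = _background(settings, background_seed)
    half = body.limb_thickness * (s / 448.0) / 2.0
    colors = body.limb_colors or ((220, 200, 80),) * 6
    # painter's order: draw far bones first so occlusion follows true depth
    depth = {(a, b): (pose[a][2] + pose[b][2]) / 2.0 for a, b, _ in BONES}
    for a, b, ci in sorted(BONES, key=lambda e: -depth[(e[0], e[1])]):
        p0, p1 = px[a], px[b]
        color = np.asarray(colors[ci % len(colors)], dtype=float)
        lo = np.floor(np.minimum(p0, p1) - half - 1.0).astype(int)
        hi = np.ceil(np.maximum(p0, p1) + half + 2.0).astype(int)
        lo = np.clip(lo, 0, s)
        hi = np.clip(hi, 0, s)
        if (hi <= lo).any():
            continue
        xs = np.arange(lo[0], hi[0])
        ys = np.arange(lo[1], hi[1])
        gx, gy = np.meshgrid(xs, ys)
        d = p1 - p0
        seg_len2 = float(d @ d)
        if seg_len2 == 0.0:
            t = np.zeros_like(gx, dtype=float)
        else:
            t = np.clip(((gx - p0[0]) * d[0] + (gy - p0[1]) * d[1]) / seg_len2, 0.0, 1.0)
        cx = p0[0] + t * d[0]
        cy = p0[1] + t * d[1]
        dist = np.hypot(gx - cx, gy - cy)
        alpha = np.clip(half + 0.5 - dist, 0.0, 1.0)[..., None]
        region = canvas[lo[1] : hi[1], lo[0] : hi[0]]
        region *= 1.0 - alpha
        region += alpha * color
    return np.clip(np.round(canvas), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# Dataset builder
# ---------------------------------------------------------------------------


@dataclass
class TrainingSample:
    """Three consecutive frames plus the normalized target pose of the last."""

    images: tuple[np.ndarray, np.ndarray, np.ndarray]
    target: Pose3D
    character_seed: int
    script_id: str
    frame_index: int


def build_dataset(
    characters: Sequence[BodyModel],
    scripts: Sequence[MotionScript],
    settings: RenderSettings,
    out_dir: str | Path,
    ankle_rule: str = "mean",
) -> "pd.DataFrame":
    """Render every (character, script) clip and write a training dataset.

    Layout: ``<out>/seq_<c>_<s>/frame_00000.png ...`` plus a per-clip
    ``targets.csv`` of normalized poses in the tracking-CSV dialect, and a
    top-level ``manifest.tsv`` with one row per training sample (three
    consecutive frame paths, the targets file, and the target frame index).
    A clip of N frames yields N-2 samples (sliding window of three).
    """
    import pandas as pd

    from .pipeline import TrackingRecord, write_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, body in enumerate(characters):
        for si, script in enumerate(scripts):
            seq = generate_motion(body, script)
            norm = normalize_sequence(seq, ankle_rule=ankle_rule)
            seq_dir = out / f"seq_{ci}_{si}"
            seq_dir.mkdir(exist_ok=True)
            paths = []
            for f in seq.frames:
                img = render_frame(f, body, settings, background_seed=f.frame_index)
                p = seq_dir / f"frame_{f.frame_index:05d}.png"
                Image.fromarray(img).save(p)
                paths.append(p.relative_to(out).as_posix())
            records = [
                TrackingRecord(
                    frame_index=f.frame_index,
                    time_s=f.timestamp,
                    raw=f.coords,
                    smoothed=f.coords,
                    scores=np.ones(N_KEYPOINTS),
                    body_score=1.0,
                )
                for f in norm.frames
            ]
            tpath = seq_dir / "targets.csv"
            write_csv(records, tpath, meta={"fps": script.fps, "kind": script.kind})
            for t in range(2, len(seq)):
                rows.append(
                    {
                        "sample_id": f"{ci}_{si}_{t}",
                        "frame0": paths[t - 2],
                        "frame1": paths[t - 1],
                        "frame2": paths[t],
                        "targets": tpath.relative_to(out).as_posix(),
                        "target_frame": t,
                        "character_seed": body.seed,
                        "script_kind": script.kind,
                        "script_id": si,
                    }
                )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return manifest


def load_manifest(out_dir: str | Path) -> "pd.DataFrame":
    """Read back a dataset manifest written by :func:`build_dataset`."""
    import pandas as pd

    return pd.read_csv(Path(out_dir) / "manifest.tsv", sep="\t")
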
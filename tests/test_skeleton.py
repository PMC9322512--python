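"""Geometry of the 24-keypoint skeleton: midpoints, normalization, angles."""

import numpy as np
import pytest

from gaitpose import skeleton as sk
from gaitpose.skeleton import KeypointID as K

from conftest import random_world_pose


def make_pose(**overrides) -> sk.Pose3D:
    """A minimal valid pose; keyword overrides set individual keypoints."""
    coords = np.arange(72, dtype=float).reshape(24, 3) / 10.0
    for name, val in overrides.items():
        coords[K[name]] = val
    return sk.Pose3D(coords)


class TestKeypointSet:
    def test_exactly_24_distinct_members_navel_first(self):
        assert len(K) == 24
        assert len({k.value for k in K}) == 24
        assert K.navel == 0

    def test_left_right_pairs_differ_only_in_suffix(self):
        lefts = {k.name[:-2] for k in K if k.name.endswith("_l")}
        rights = {k.name[:-2] for k in K if k.name.endswith("_r")}
        assert lefts == rights
        assert len(lefts) == 11


class TestMidpoints:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((1, 0, 0), (-1, 0, 0), (0, 0, 0)),
            ((0.2, 1.8, 0.1), (0.4, 1.8, -0.1), (0.3, 1.8, 0.0)),
            ((0.7, -0.2, 3.0), (0.7, -0.2, 3.0), (0.7, -0.2, 3.0)),
        ],
    )
    def test_head_center_is_ear_midpoint(self, a, b, expected):
        pose = make_pose(ear_l=a, ear_r=b)
        np.testing.assert_allclose(sk.head_center(pose), expected, atol=1e-15)

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ((0.5, 1.2, 0), (-0.5, 1.2, 0), (0, 1.2, 0)),
            ((0.7, -0.2, 3.0), (0.7, -0.2, 3.0), (0.7, -0.2, 3.0)),
        ],
    )
    def test_neck_is_shoulder_midpoint(self, a, b, expected):
        pose = make_pose(shoulder_l=a, shoulder_r=b)
        np.testing.assert_allclose(sk.neck_point(pose), expected, atol=1e-15)

    def test_midpoints_match_arithmetic_mean_on_random_poses(self, rng):
        for seed in range(5):
            pose = random_world_pose(seed)
            np.testing.assert_allclose(
                sk.head_center(pose), (pose[K.ear_l] + pose[K.ear_r]) / 2, atol=1e-12
            )
            np.testing.assert_allclose(
                sk.neck_point(pose),
                (pose[K.shoulder_l] + pose[K.shoulder_r]) / 2,
                atol=1e-12,
            )

    def test_nonfinite_ears_rejected(self):
        pose = make_pose(ear_l=(np.nan, 0, 0))
        with pytest.raises(sk.InvalidPoseError):
            sk.head_center(pose)


class TestNormalize:
    @pytest.mark.parametrize("seed", range(6))
    def test_reference_lengths_are_one(self, seed):
        norm = sk.normalize_pose(random_world_pose(seed))
        assert np.linalg.norm(norm[K.navel]) == 0
        assert np.linalg.norm(sk.head_center(norm)) == pytest.approx(1.0, abs=1e-12)
        mean_ankle = 0.5 * (
            np.linalg.norm(norm[K.ankle_l]) + np.linalg.norm(norm[K.ankle_r])
        )
        assert mean_ankle == pytest.approx(1.0, abs=1e-12)

    def test_idempotent(self):
        pose = random_world_pose(7)
        once = sk.normalize_pose(pose)
        twice = sk.normalize_pose(once)
        np.testing.assert_allclose(twice.coords, once.coords, rtol=1e-12, atol=1e-12)

    def test_already_normalized_pose_unchanged(self):
        pose = sk.normalize_pose(random_world_pose(3))
        again = sk.normalize_pose(pose)
        np.testing.assert_allclose(again.coords, pose.coords, rtol=1e-12, atol=1e-12)

    def test_affine_oracle(self):
        """Hand-computed translation and per-half scales on a stated pose."""
        pose = random_world_pose(11, transform=False)
        coords = pose.coords.copy()
        navel = np.array([10.0, 20.0, 30.0])
        coords = coords - coords[K.navel] + navel
        hc = 0.5 * (coords[K.ear_l] + coords[K.ear_r])
        coords_upper_scale = 2.0 / np.linalg.norm(hc - navel)
        mean_ankle = 0.5 * (
            np.linalg.norm(coords[K.ankle_l] - navel)
            + np.linalg.norm(coords[K.ankle_r] - navel)
        )
        lower_scale_to4 = 4.0 / mean_ankle
        # force head-center distance 2 and mean ankle distance 4
        for kp in sk.UPPER_KEYPOINTS:
            coords[kp] = navel + (coords[kp] - navel) * coords_upper_scale
        for kp in sk.LOWER_KEYPOINTS:
            coords[kp] = navel + (coords[kp] - navel) * lower_scale_to4
        norm = sk.normalize_pose(sk.Pose3D(coords))
        expected = np.zeros((24, 3))
        for kp in sk.UPPER_KEYPOINTS:
            expected[kp] = (coords[kp] - navel) * 0.5
        for kp in sk.LOWER_KEYPOINTS:
            expected[kp] = (coords[kp] - navel) * 0.25
        np.testing.assert_allclose(norm.coords, expected, rtol=1e-12, atol=1e-12)

    def test_ankle_rules(self):
        pose = random_world_pose(5)
        for rule, kp in (("left", K.ankle_l), ("right", K.ankle_r)):
            norm = sk.normalize_pose(pose, ankle_rule=rule)
            assert np.linalg.norm(norm[kp]) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_pose_rejected(self):
        pose = make_pose(ear_l=(0, 0, 0), ear_r=(0, 0, 0), navel=(0, 0, 0))
        with pytest.raises(sk.DegeneratePoseError):
            sk.normalize_pose(pose)

    def test_per_sequence_mode_freezes_first_frame_scales(self):
        from gaitpose import synthetic as syn

        body = syn.make_character(2)
        seq = syn.generate_walk(body, syn.MotionScript(duration=0.3, fps=30))
        per_seq = sk.normalize_sequence(seq, mode="per_sequence")
        # first frame matches per-frame normalization; later frames keep scale
        np.testing.assert_allclose(
            per_seq.frames[0].coords,
            sk.normalize_pose(seq.frames[0]).coords,
            atol=1e-12,
        )
        for f, orig in zip(per_seq.frames, seq.frames):
            assert np.linalg.norm(f.coords[K.navel]) == 0
            # segment length ratios preserved within each half
            orig_knee = np.linalg.norm(orig.coords[K.knee_l] - orig.coords[K.hip_l])
            new_knee = np.linalg.norm(f.coords[K.knee_l] - f.coords[K.hip_l])
            ref = np.linalg.norm(
                seq.frames[0].coords[K.knee_l] - seq.frames[0].coords[K.hip_l]
            )
            new_ref = np.linalg.norm(
                per_seq.frames[0].coords[K.knee_l] - per_seq.frames[0].coords[K.hip_l]
            )
            assert new_knee / orig_knee == pytest.approx(new_ref / ref, rel=1e-9)


def law_of_cosines_angle(u, v):
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    c = (nu**2 + nv**2 - np.linalg.norm(u - v) ** 2) / (2 * nu * nv)
    return np.degrees(np.arccos(np.clip(c, -1, 1)))


class TestVectorAngle:
    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ((1, 2, 3), (1, 2, 3), 0.0),
            ((1, 2, 3), (-1, -2, -3), 180.0),
            ((1, 0, 0), (1, 1, 0), 45.0),
            ((1, 0, 0), (0, 1, 0), 90.0),
        ],
    )
    def test_closed_form(self, u, v, expected):
        assert sk.vector_angle(u, v) == pytest.approx(expected, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(sk.DegeneratePoseError):
            sk.vector_angle((0, 0, 0), (1, 0, 0))

    def test_matches_law_of_cosines_on_1000_random_pairs(self, rng):
        u = rng.standard_normal((1000, 3))
        v = rng.standard_normal((1000, 3))
        for ui, vi in zip(u, v):
            assert sk.vector_angle(ui, vi) == pytest.approx(
                law_of_cosines_angle(ui, vi), abs=1e-9
            )


class TestLimbAngles:
    def test_straight_leg_reads_zero_flexion(self):
        pose = make_pose(
            hip_l=(0, 1, 0), knee_l=(0, 0.5, 0), ankle_l=(0, 0, 0), toe_l=(0.2, 0, 0)
        )
        assert sk.limb_angles(pose, "vector").knee_l == pytest.approx(180.0, abs=1e-9)
        assert sk.limb_angles(pose, "flexion").knee_l == pytest.approx(0.0, abs=1e-9)

    def test_right_angle_knee(self):
        pose = make_pose(
            hip_r=(0, 1, 0), knee_r=(0, 0, 0), ankle_r=(0, 0, -0.5)
        )
        assert sk.limb_angles(pose, "vector").knee_r == pytest.approx(90.0, abs=1e-9)
        assert sk.limb_angles(pose, "flexion").knee_r == pytest.approx(90.0, abs=1e-9)

    def test_conventions_are_supplementary(self):
        pose = random_world_pose(21)
        vec = sk.limb_angles(pose, "vector")
        flex = sk.limb_angles(pose, "flexion")
        for j in sk.JointAngles.JOINTS:
            assert getattr(vec, j) + getattr(flex, j) == pytest.approx(180.0, abs=1e-9)
            assert 0.0 <= getattr(vec, j) <= 180.0

    @pytest.mark.parametrize("seed", range(4))
    def test_similarity_invariance(self, seed, rng):
        pose = random_world_pose(seed, transform=False)
        a = rng.standard_normal((3, 3))
        q, _ = np.linalg.qr(a)
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        s = float(rng.uniform(0.2, 5.0))
        t = rng.uniform(-100, 100, size=3)
        moved = sk.Pose3D(pose.coords @ q.T * s + t)
        ref = sk.limb_angles(pose)
        got = sk.limb_angles(moved)
        for j in sk.JointAngles.JOINTS:
            assert getattr(got, j) == pytest.approx(getattr(ref, j), abs=1e-9)

    def test_matches_dot_product_oracle_per_joint(self):
        pose = random_world_pose(33)
        vec = sk.limb_angles(pose, "vector")
        assert vec.knee_l == pytest.approx(
            law_of_cosines_angle(
                pose[K.hip_l] - pose[K.knee_l], pose[K.ankle_l] - pose[K.knee_l]
            ),
            abs=1e-9,
        )
        assert vec.hip_r == pytest.approx(
            law_of_cosines_angle(
                pose[K.navel] - pose[K.hip_r], pose[K.knee_r] - pose[K.hip_r]
            ),
            abs=1e-9,
        )
        assert vec.ankle_l == pytest.approx(
            law_of_cosines_angle(
                pose[K.knee_l] - pose[K.ankle_l], pose[K.toe_l] - pose[K.ankle_l]
            ),
            abs=1e-9,
        )
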
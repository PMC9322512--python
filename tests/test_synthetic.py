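"""Synthetic characters, procedural motions and the square-frame renderer."""

import math

import numpy as np
import pytest

from gaitpose import skeleton as sk
from gaitpose import synthetic as syn
from gaitpose.skeleton import KeypointID as K


def body_yaw(pose):
    """Heading recovered from the hip line (left = hip_l - hip_r direction)."""
    left = pose[K.hip_l] - pose[K.hip_r]
    return math.atan2(-left[2], left[0])


class TestMakeCharacter:
    def test_deterministic_in_seed(self):
        assert syn.make_character(42) == syn.make_character(42)

    def test_zero_variation_reproduces_template(self):
        body = syn.make_character(7, variation=0.0)
        assert body.thigh == syn._TEMPLATE["thigh"]
        assert body.torso == syn._TEMPLATE["torso"]

    def test_90_seeds_give_90_distinct_characters(self):
        bodies = [syn.make_character(s) for s in range(90)]
        sigs = {(b.thigh, b.torso, b.shoulder_width) for b in bodies}
        assert len(sigs) == 90

    def test_negative_seed_rejected(self):
        with pytest.raises(ValueError):
            syn.make_character(-1)


class TestCircleWalk:
    script = syn.MotionScript(kind="circle_walk", duration=7.0, fps=30.0, diameter=1.0, laps=2)

    def test_pelvis_radius_is_half_diameter(self):
        seq = syn.generate_walk(syn.make_character(0), self.script)
        navel = seq.as_array()[:, K.navel]
        radius = np.hypot(navel[:, 0], navel[:, 2])
        np.testing.assert_allclose(radius, 0.5, atol=1e-12)

    def test_cumulative_heading_is_laps_times_360(self):
        seq = syn.generate_walk(syn.make_character(0), self.script)
        yaws = np.unwrap([body_yaw(f) for f in seq.frames])
        n = len(seq)
        total = abs(yaws[-1] - yaws[0]) * n / (n - 1)  # extend to the full duration
        assert math.degrees(total) == pytest.approx(720.0, abs=1e-6)

    def test_clockwise_reverses_heading_sign(self):
        cw = syn.MotionScript(kind="circle_walk", duration=2.0, direction="cw")
        ccw = syn.MotionScript(kind="circle_walk", duration=2.0, direction="ccw")
        b = syn.make_character(0)
        y_cw = np.unwrap([body_yaw(f) for f in syn.generate_walk(b, cw).frames])
        y_ccw = np.unwrap([body_yaw(f) for f in syn.generate_walk(b, ccw).frames])
        assert (y_cw[-1] - y_cw[0]) * (y_ccw[-1] - y_ccw[0]) < 0

    def test_knee_series_left_equals_right_shifted_half_cycle(self):
        # cadence 2 steps/s -> 1 gait cycle/s -> half cycle = 15 frames at 30 fps
        script = syn.MotionScript(kind="circle_walk", duration=4.0, fps=30.0, cadence=2.0)
        seq = syn.generate_walk(syn.make_character(3), script)
        knees_l = np.array([sk.limb_angles(f).knee_l for f in seq.frames])
        knees_r = np.array([sk.limb_angles(f).knee_r for f in seq.frames])
        shift = 15
        assert np.abs(knees_r[:-shift] - knees_l[shift:]).max() < 1e-9

    def test_static_script_freezes_the_pose(self):
        script = syn.MotionScript(
            kind="circle_walk", duration=0.5, fps=30.0, cadence=0.0, laps=0.0,
            hip_amplitude=0.0, knee_amplitude=0.0, ankle_amplitude=0.0,
            arm_swing_amplitude=0.0,
        )
        seq = syn.generate_walk(syn.make_character(1), script)
        arr = seq.as_array()
        np.testing.assert_allclose(arr, np.broadcast_to(arr[0], arr.shape), atol=1e-12)

    def test_wrong_kind_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_walk(syn.make_character(0), syn.MotionScript(kind="dance"))


class TestRotation:
    def test_navel_fixed_and_frame_count(self):
        script = syn.MotionScript(kind="rotation_in_place", duration=10.0, fps=30.0, turn_rate=36.0)
        seq = syn.generate_rotation(syn.make_character(2), script)
        assert len(seq) == 300
        navel = seq.as_array()[:, K.navel]
        np.testing.assert_allclose(navel, np.broadcast_to(navel[0], navel.shape), atol=1e-12)
        yaws = np.unwrap([body_yaw(f) for f in seq.frames])
        total = (yaws[-1] - yaws[0]) * len(seq) / (len(seq) - 1)
        assert math.degrees(abs(total)) == pytest.approx(360.0, abs=1e-6)

    def test_wrist_traces_circle_of_arm_span_radius(self):
        body = syn.make_character(4)
        script = syn.MotionScript(kind="rotation_in_place", duration=5.0, fps=30.0)
        seq = syn.generate_rotation(body, script)
        wrist = seq.as_array()[:, K.wrist_l]
        navel = seq.as_array()[:, K.navel]
        radius = np.hypot(wrist[:, 0] - navel[:, 0], wrist[:, 2] - navel[:, 2])
        expected = body.shoulder_width / 2 + body.upper_arm + body.lower_arm
        np.testing.assert_allclose(radius, np.full_like(radius, expected), atol=1e-9)


class TestDance:
    def test_deterministic_in_seed(self):
        body = syn.make_character(5)
        s = syn.MotionScript(kind="dance", duration=1.0, fps=30.0, seed=9)
        a = syn.generate_dance(body, s).as_array()
        b = syn.generate_dance(body, s).as_array()
        np.testing.assert_array_equal(a, b)

    def test_knee_flexion_stays_within_limits(self):
        body = syn.make_character(5)
        s = syn.MotionScript(kind="dance", duration=2.0, fps=30.0, seed=1)
        seq = syn.generate_dance(body, s)
        knees = np.array(
            [[sk.limb_angles(f).knee_l, sk.limb_angles(f).knee_r] for f in seq.frames]
        )
        assert knees.min() >= -1e-9
        assert knees.max() <= 50.0 + 1e-9

    def test_joint_drive_is_band_limited(self):
        body = syn.make_character(5)
        s = syn.MotionScript(kind="dance", duration=8.0, fps=30.0, seed=2, smoothness=1.5)
        seq = syn.generate_dance(body, s)
        knee = np.array([sk.limb_angles(f).knee_l for f in seq.frames])
        spec = np.abs(np.fft.rfft(knee - knee.mean())) ** 2
        freqs = np.fft.rfftfreq(len(knee), 1.0 / 30.0)
        # the |.| fold that keeps knee flexion nonnegative doubles frequencies,
        # so allow a small harmonic tail; white noise would put ~60% up here
        high = spec[freqs > 4 * s.smoothness].sum()
        assert high / spec.sum() < 0.05


class TestRenderer:
    def test_default_size_is_448(self):
        body = syn.make_character(0)
        pose = syn.generate_walk(body, syn.MotionScript(duration=0.1)).frames[0]
        img = syn.render_frame(pose, body)
        assert img.shape == (448, 448, 3)
        assert img.dtype == np.uint8

    def test_corners_keep_background_and_body_is_drawn(self):
        body = syn.make_character(0)
        pose = syn.generate_walk(body, syn.MotionScript(duration=0.1)).frames[0]
        settings = syn.RenderSettings(image_side=112, background_level=32)
        img = syn.render_frame(pose, body, settings)
        for r, c in ((0, 0), (0, -1), (-1, 0), (-1, -1)):
            np.testing.assert_array_equal(img[r, c], (32, 32, 32))
        assert (img != 32).any()

    def test_projection_matches_pinhole_oracle(self):
        body = syn.make_character(6)
        pose = syn.generate_walk(body, syn.MotionScript(duration=0.1)).frames[1]
        settings = syn.RenderSettings(image_side=448, camera_distance=3.0, focal_scale=1.1)
        px = syn.project_keypoints(pose, settings)
        f = 1.1 * 448
        rel = pose.coords - pose.coords[K.navel]
        for i in range(24):
            z = 3.0 + rel[i, 2]
            u = 224.0 + f * rel[i, 0] / z
            v = 224.0 - f * rel[i, 1] / z
            assert abs(px[i, 0] - u) < 0.5 and abs(px[i, 1] - v) < 0.5

    def test_render_is_deterministic(self):
        body = syn.make_character(1)
        pose = syn.generate_walk(body, syn.MotionScript(duration=0.1)).frames[0]
        settings = syn.RenderSettings(image_side=64)
        np.testing.assert_array_equal(
            syn.render_frame(pose, body, settings), syn.render_frame(pose, body, settings)
        )

    def test_out_of_frame_raises(self):
        body = syn.make_character(0)
        pose = syn.generate_walk(body, syn.MotionScript(duration=0.1)).frames[0]
        settings = syn.RenderSettings(image_side=64, focal_scale=3.0)  # zoomed way in
        with pytest.raises(syn.OutOfFrameError):
            syn.render_frame(pose, body, settings)

    def test_odd_or_small_sides_rejected(self):
        with pytest.raises(ValueError):
            syn.RenderSettings(image_side=63)
        with pytest.raises(ValueError):
            syn.RenderSettings(image_side=32)


class TestBuildDataset:
    def test_layout_counts_and_target_normalization(self, micro_dataset):
        out, manifest = micro_dataset
        # 6-frame clip -> 4 sliding-window samples
        assert len(manifest) == 4
        reloaded = syn.load_manifest(out)
        assert reloaded.equals(manifest.reset_index(drop=True))
        from gaitpose.pipeline import read_csv

        records, meta = read_csv(out / "seq_0_0" / "targets.csv")
        assert len(records) == 6
        for rec in records:
            pose = sk.Pose3D(rec.raw)
            assert np.linalg.norm(sk.head_center(pose)) == pytest.approx(1.0, abs=1e-9)
            renorm = sk.normalize_pose(pose)
            np.testing.assert_allclose(renorm.coords, pose.coords, atol=1e-9)

    def test_manifest_references_existing_frames(self, micro_dataset):
        out, manifest = micro_dataset
        for row in manifest.itertuples():
            for col in ("frame0", "frame1", "frame2"):
                assert (out / getattr(row, col)).exists()
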
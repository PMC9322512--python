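import numpy as np
import pytest

from gaitpose import synthetic as syn
from gaitpose.skeleton import Pose3D


def random_world_pose(seed: int = 0, transform: bool = True) -> Pose3D:
    """An anatomically plausible pose in arbitrary world coordinates.

    Draws a random character and a random dance posture, then (optionally)
    applies a random rigid rotation, uniform scale and translation so that
    nothing is axis-aligned or unit-scaled.
    """
    rng = np.random.default_rng(seed)
    body = syn.make_character(int(rng.integers(0, 2**16)))
    script = syn.MotionScript(kind="dance", duration=0.6, fps=30, seed=int(rng.integers(0, 2**16)))
    seq = syn.generate_dance(body, script)
    pose = seq.frames[int(rng.integers(0, len(seq)))]
    coords = pose.coords
    if transform:
        a = rng.standard_normal((3, 3))
        q, _ = np.linalg.qr(a)
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        s = float(rng.uniform(0.5, 3.0))
        t = rng.uniform(-10, 10, size=3)
        coords = coords @ q.T * s + t
    return Pose3D(coords, pose.frame_index, pose.timestamp)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def micro_dataset(tmp_path_factory):
    """A tiny on-disk dataset: one character, 6-frame walk, 64 px frames."""
    out = tmp_path_factory.mktemp("micro_data")
    body = syn.make_character(1)
    script = syn.MotionScript(kind="circle_walk", duration=0.2, fps=30.0)
    settings = syn.RenderSettings(image_side=64)
    manifest = syn.build_dataset([body], [script], settings, out)
    return out, manifest
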
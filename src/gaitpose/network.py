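"""Residual CNN mapping three stacked RGB frames to pose volumes.

The network consumes the channel-concatenation of three consecutive frames
(9 input channels) and emits, per keypoint, one raw-score heat volume and
three tanh-bounded offset volumes on a G x G x G grid — the codec's
representation.  The G^3 volume is realized as G depth slices of a G x G
spatial map, so the backbone stays two-dimensional.

No deep-learning framework is assumed: convolutions are im2col matrix
multiplies and the backward passes are written out analytically (a
finite-difference check in the test suite guards them).  Optimization is
Adam with seeded shuffling, reproducible end to end.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .codec import CubeSpec, PoseVolumes, decode, probability_normalize
from .skeleton import MotionSequence, N_KEYPOINTS, Pose3D

__all__ = [
    "NetworkConfig",
    "TrainState",
    "PoseNet",
    "build_model",
    "loss",
    "train",
    "infer_sequence",
    "load_model",
    "load_samples",
]

_DTYPE = np.float32


@dataclass
class NetworkConfig:
    """Architecture and optimization settings.

    The ``tiny`` preset (G=14, 112 px input) is the desk-scale path; the
    ``resnet34_like`` preset mirrors a 34-layer residual backbone at the full
    448 px / G=28 scale and keeps the low learning rates (1e-5 to 1e-6) that
    scale requires, but is far too slow to train without an accelerator.
    """

    preset: str = "tiny"
    input_side: int = 112
    grid_size: int = 14
    half_side: float = 1.5
    learning_rate: float = 1e-4
    batch_size: int = 20
    epochs: int = 300
    seed: int = 0
    n_frames: int = 3  # frames per input window (fixed contract)
    tiny_width: int = 64  # channel width of the tiny preset's second stage

    def __post_init__(self) -> None:
        if self.n_frames != 3:
            raise ValueError("the input contract is exactly 3 stacked frames")
        factor = {"tiny": 8, "resnet34_like": 16}.get(self.preset)
        if factor is None:
            raise ValueError(f"unknown preset {self.preset!r}")
        if self.input_side != factor * self.grid_size:
            raise ValueError(
                f"preset {self.preset!r} downsamples by {factor}: "
                f"input_side must be {factor}*grid_size"
            )

    @classmethod
    def tiny(cls, **kw) -> "NetworkConfig":
        kw.setdefault("learning_rate", 1e-3)
        kw.setdefault("batch_size", 10)
        return cls(preset="tiny", input_side=112, grid_size=14, **kw)

    @classmethod
    def resnet34_like(cls, **kw) -> "NetworkConfig":
        kw.setdefault("learning_rate", 1e-5)
        return cls(preset="resnet34_like", input_side=448, grid_size=28, **kw)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(B,C,H,W) -> (B,OH,OW,C*k*k) patch matrix."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    w = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    w = w[:, :, ::stride, ::stride]
    b, c, oh, ow = w.shape[:4]
    return np.ascontiguousarray(w.transpose(0, 2, 3, 1, 4, 5)).reshape(b, oh, ow, c * k * k)


class Conv2d:
    """Convolution with bias; weight layout (Cout, Cin, k, k)."""

    def __init__(self, cin: int, cout: int, k: int, stride: int = 1, pad: int = 0, rng=None):
        self.cin, self.cout, self.k, self.stride, self.pad = cin, cout, k, stride, pad
        scale = np.sqrt(2.0 / (cin * k * k))
        rng = rng or np.random.default_rng(0)
        self.w = (rng.standard_normal((cout, cin, k, k)) * scale).astype(_DTYPE)
        self.b = np.zeros(cout, dtype=_DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.k == 1 and self.stride == 1 and self.pad == 0:
            # pointwise conv: plain matrix multiply over the channel axis
            b, c, h, w = x.shape
            xf = np.ascontiguousarray(x.transpose(0, 2, 3, 1)).reshape(-1, c)
            y = xf @ self.w.reshape(self.cout, c).T + self.b
            self._cache = (xf, x.shape)
            return np.ascontiguousarray(
                y.reshape(b, h, w, self.cout).transpose(0, 3, 1, 2)
            )
        cols = _im2col(x, self.k, self.stride, self.pad)
        b, oh, ow, _ = cols.shape
        y = cols.reshape(-1, cols.shape[-1]) @ self.w.reshape(self.cout, -1).T
        y += self.b
        self._cache = (cols, x.shape)
        return np.ascontiguousarray(
            y.reshape(b, oh, ow, self.cout).transpose(0, 3, 1, 2)
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.k == 1 and self.stride == 1 and self.pad == 0:
            xf, xshape = self._cache
            b, c, h, w = xshape
            dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
            self.db += dyf.sum(axis=0)
            self.dw += (dyf.T @ xf).reshape(self.w.shape)
            dx = dyf @ self.w.reshape(self.cout, c)
            return np.ascontiguousarray(
                dx.reshape(b, h, w, c).transpose(0, 3, 1, 2)
            )
        cols, xshape = self._cache
        b, oh, ow, ckk = cols.shape
        dyf = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(-1, self.cout)
        self.db += dyf.sum(axis=0)
        self.dw += (dyf.T @ cols.reshape(-1, ckk)).reshape(self.w.shape)
        dcols = (dyf @ self.w.reshape(self.cout, -1)).reshape(b, oh, ow, self.cin, self.k, self.k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)
        _, c, h, w = xshape
        p, s, k = self.pad, self.stride, self.k
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=_DTYPE)
        for ki in range(k):
            for kj in range(k):
                dxp[:, :, ki : ki + s * oh : s, kj : kj + s * ow : s] += dcols[..., ki, kj]
        return dxp[:, :, p : p + h, p : p + w] if p else dxp

    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0)

    def params(self):
        return []


class GlobalContext:
    """Adds a globally pooled feature summary back to every position.

    The head is convolutional, so each output cell only sees its receptive
    field; body-wide cues (which way the subject faces) live outside it for
    extremities.  A pooled bottleneck (mean over space -> two dense layers ->
    broadcast add) routes that context everywhere at negligible cost.
    """

    def __init__(self, c: int, rng=None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / c)
        self.w1 = (rng.standard_normal((c, c)) * scale).astype(_DTYPE)
        self.b1 = np.zeros(c, dtype=_DTYPE)
        self.w2 = (rng.standard_normal((c, c)) * scale * 0.1).astype(_DTYPE)
        self.b2 = np.zeros(c, dtype=_DTYPE)
        self.dw1 = np.zeros_like(self.w1)
        self.db1 = np.zeros_like(self.b1)
        self.dw2 = np.zeros_like(self.w2)
        self.db2 = np.zeros_like(self.b2)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        m = x.mean(axis=(2, 3))  # (B, C)
        h = m @ self.w1.T + self.b1
        hr = np.where(h > 0, h, 0)
        g = hr @ self.w2.T + self.b2
        self._cache = (m, h > 0, hr, x.shape)
        return x + g[:, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        m, mask, hr, xshape = self._cache
        dg = dy.sum(axis=(2, 3))  # (B, C)
        self.dw2 += dg.T @ hr
        self.db2 += dg.sum(axis=0)
        dh = np.where(mask, dg @ self.w2, 0)
        self.dw1 += dh.T @ m
        self.db1 += dh.sum(axis=0)
        dm = dh @ self.w1  # (B, C)
        n_px = xshape[2] * xshape[3]
        return dy + (dm / n_px)[:, :, None, None]

    def params(self):
        return [
            (self.w1, self.dw1), (self.b1, self.db1),
            (self.w2, self.dw2), (self.b2, self.db2),
        ]


class ResBlock:
    """conv3x3 -> relu -> conv3x3 plus a (possibly projected) shortcut."""

    def __init__(self, cin: int, cout: int, stride: int = 1, rng=None):
        self.conv1 = Conv2d(cin, cout, 3, stride, 1, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, 1, 1, rng)
        self.proj = Conv2d(cin, cout, 1, stride, 0, rng) if (stride != 1 or cin != cout) else None
        self.relu2 = ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        sc = self.proj.forward(x) if self.proj is not None else x
        return self.relu2.forward(y + sc)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        d = self.relu2.backward(dy)
        dx = self.conv1.backward(self.relu1.backward(self.conv2.backward(d)))
        dx += self.proj.backward(d) if self.proj is not None else d
        return dx

    def params(self):
        out = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            out += self.proj.params()
        return out


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


class PoseNet:
    """Residual CNN from a 9-channel frame stack to raw pose volumes."""

    def __init__(self, config: NetworkConfig):
        self.config = config
        g = config.grid_size
        rng = np.random.default_rng(config.seed)
        head_out = N_KEYPOINTS * 4 * g
        if config.preset == "tiny":
            w = config.tiny_width
            self.layers: list = [
                Conv2d(9, 16, 5, 4, 2, rng), ReLU(),
                Conv2d(16, w, 3, 2, 1, rng), ReLU(),
                ResBlock(w, w, 1, rng),
                GlobalContext(w, rng),
                ResBlock(w, w, 1, rng),
                Conv2d(w, head_out, 1, 1, 0, rng),
            ]
            # near-zero head init: the targets are sparse one-hot grids, and a
            # large initial output collapses first, poisoning Adam's second
            # moment for the slow memorization phase that follows
            self.layers[-1].w *= 0.01
        else:  # resnet34_like: stem + [3, 4, 6, 3] residual blocks
            layers: list = [Conv2d(9, 64, 7, 4, 3, rng), ReLU()]
            plan = [(64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 1)]
            cin = 64
            for cout, nblocks, stride in plan:
                for bi in range(nblocks):
                    layers.append(ResBlock(cin, cout, stride if bi == 0 else 1, rng))
                    cin = cout
            layers.append(Conv2d(cin, head_out, 1, 1, 0, rng))
            self.layers = layers

    # -- parameter plumbing --------------------------------------------------
    def params(self) -> list[tuple[np.ndarray, np.ndarray]]:
        out = []
        for layer in self.layers:
            out += layer.params()
        return out

    def zero_grad(self) -> None:
        for _, g in self.params():
            g[...] = 0

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params())

    # -- forward / backward --------------------------------------------------
    def _forward_layers(self, x: np.ndarray) -> np.ndarray:
        """Backbone + head: (B,9,S,S) -> head maps (B, 24*4*G, G, G)."""
        y = np.asarray(x, dtype=_DTYPE)
        for layer in self.layers:
            y = layer.forward(y)
        return y

    def _backward_layers(self, dy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)

    def forward_raw(self, x: np.ndarray) -> np.ndarray:
        """(B,9,S,S) float32 -> raw volumes (B,24,4,G,G,G), codec layout.

        Channel c of the head map encodes (keypoint, group, z-slice); the
        spatial map columns are the grid x axis and the rows the grid y axis
        *flipped* (image rows grow downward, grid y grows upward — keeping
        the head map spatially aligned with the image lets the shared-weight
        convolutions place heat where the limb appears).  Group 0 is the
        heat score, groups 1..3 the x/y/z offsets (pre-tanh).
        """
        y = self._forward_layers(x)
        b = y.shape[0]
        g = self.config.grid_size
        vol = y.reshape(b, N_KEYPOINTS, 4, g, g, g)  # (B,kp,grp,z,row,x)
        return vol.transpose(0, 1, 2, 5, 4, 3)[:, :, :, :, ::-1, :]  # -> (...,x,y,z)

    def backward(self, dvol: np.ndarray) -> None:
        b = dvol.shape[0]
        g = self.config.grid_size
        dy = np.ascontiguousarray(
            dvol[:, :, :, :, ::-1, :].transpose(0, 1, 2, 5, 4, 3)
        ).reshape(b, N_KEYPOINTS * 4 * g, g, g)
        self._backward_layers(dy)

    def predict_volumes(self, x: np.ndarray) -> list[PoseVolumes]:
        """Forward pass to finished volumes: softmax heat, tanh offsets."""
        raw = self.forward_raw(x)
        spec = CubeSpec(self.config.half_side, self.config.grid_size)
        out = []
        for b in range(raw.shape[0]):
            heat = np.stack(
                [probability_normalize(raw[b, kp, 0]) for kp in range(N_KEYPOINTS)]
            )
            offs = np.tanh(raw[b, :, 1:4].astype(float))
            out.append(PoseVolumes(heat, offs, spec))
        return out

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> Path:
        path = Path(path)
        if path.suffix != ".npz":
            path = path.with_suffix(path.suffix + ".npz")
        arrays = {f"p{i}": p for i, (p, _) in enumerate(self.params())}
        np.savez(path, config=json.dumps(asdict(self.config)), **arrays)
        return path


def load_model(path: str | Path) -> PoseNet:
    with np.load(path, allow_pickle=False) as data:
        config = NetworkConfig(**json.loads(str(data["config"])))
        model = PoseNet(config)
        for i, (p, _) in enumerate(model.params()):
            p[...] = data[f"p{i}"]
    return model


def build_model(config: NetworkConfig) -> PoseNet:
    """Construct the residual network for ``config`` (deterministic in seed)."""
    return PoseNet(config)


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


def loss(pred: PoseVolumes, target: PoseVolumes) -> float:
    """Sum over the four output groups (heat, x/y/z offsets) of the MSE.

    Each group's error is averaged over every cell of every keypoint, so the
    value is 0 iff the volumes agree exactly, and symmetric in its arguments.
    """
    if pred.heat.shape != target.heat.shape or pred.offsets.shape != target.offsets.shape:
        raise ValueError("pred/target volume shapes differ")
    total = float(np.mean((pred.heat - target.heat) ** 2))
    for a in range(3):
        total += float(np.mean((pred.offsets[:, a] - target.offsets[:, a]) ** 2))
    return total


def _sparse_targets(
    poses: Sequence[Pose3D], spec: CubeSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Target cell indices (N,24,3) and in-cell offsets (N,24,3)."""
    cells = np.zeros((len(poses), N_KEYPOINTS, 3), dtype=np.int64)
    offs = np.zeros((len(poses), N_KEYPOINTS, 3), dtype=_DTYPE)
    for n, pose in enumerate(poses):
        for kp in range(N_KEYPOINTS):
            c = spec.point_to_cell(pose.coords[kp], name=f"keypoint {kp}")
            cells[n, kp] = c
            offs[n, kp] = (pose.coords[kp] - spec.cell_center(c)) / (spec.cell_size / 2)
    return cells, offs


def _batch_loss_grad(
    raw: np.ndarray, cells: np.ndarray, offs: np.ndarray
) -> tuple[float, np.ndarray]:
    """L2 training loss on raw head output against sparse one-hot targets.

    Heat: squared error of the raw scores against the one-hot occupancy,
    summed over the grid and averaged over keypoints and batch (the
    per-keypoint normalization keeps the localization term commensurate
    with the offset terms; a per-cell mean would scale it down by G^3 and
    the network would stop learning localization).  Offsets: squared error
    of tanh(raw) against the true in-cell offset, evaluated at the occupied
    cell (the only cell decoding ever reads), averaged over keypoints and
    batch.  Returns the summed loss and d(loss)/d(raw).

    Layout-agnostic in the three spatial axes: ``cells`` must index the same
    axis order as ``raw`` (the training loop keeps the head's native z,y,x
    order to avoid large transposes).
    """
    b, nk = raw.shape[0], raw.shape[1]
    bi = np.arange(b)[:, None]
    ki = np.arange(nk)[None, :]
    ci, cj, ck = cells[..., 0], cells[..., 1], cells[..., 2]

    grad = np.zeros_like(raw)
    diff = raw[:, :, 0].astype(_DTYPE).copy()
    diff[bi, ki, ci, cj, ck] -= 1.0
    total = float(np.sum(diff.astype(np.float64) ** 2)) / (b * nk)
    grad[:, :, 0] = (2.0 / (b * nk)) * diff

    for a in range(3):
        z = raw[bi, ki, a + 1, ci, cj, ck]
        v = np.tanh(z)
        e = v - offs[..., a]
        total += float(np.mean(e.astype(np.float64) ** 2))
        ga = np.zeros_like(diff)
        ga[bi, ki, ci, cj, ck] = (2.0 / e.size) * e * (1.0 - v**2)
        grad[:, :, a + 1] = ga
    return total, grad


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


@dataclass
class TrainState:
    """Bookkeeping returned by :func:`train`."""

    epoch: int
    losses: list[float]
    checkpoint: Path | None = None

    @property
    def final_loss(self) -> float:
        return self.losses[-1]


class _Adam:
    def __init__(self, params, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def load_samples(
    manifest, root: str | Path
) -> tuple[np.ndarray, list[Pose3D]]:
    """Materialize a dataset manifest: (N,9,S,S) float32 stacks and targets."""
    from PIL import Image

    from .pipeline import read_csv

    root = Path(root)
    targets_cache: dict[str, list] = {}
    xs, ys = [], []
    for row in manifest.itertuples():
        imgs = []
        for col in ("frame0", "frame1", "frame2"):
            arr = np.asarray(Image.open(root / getattr(row, col)), dtype=_DTYPE) / 255.0
            imgs.append(arr.transpose(2, 0, 1))
        xs.append(np.concatenate(imgs, axis=0))
        tfile = str(row.targets)
        if tfile not in targets_cache:
            records, _ = read_csv(root / tfile)
            targets_cache[tfile] = records
        rec = targets_cache[tfile][int(row.target_frame)]
        ys.append(Pose3D(rec.raw, rec.frame_index, rec.time_s))
    return np.stack(xs), ys


def train(
    model: PoseNet,
    manifest,
    config: NetworkConfig | None = None,
    root: str | Path = ".",
    out_dir: str | Path | None = None,
    log_every: int = 10,
) -> TrainState:
    """Fit the network with Adam on a rendered dataset.

    ``manifest`` is the dataset manifest DataFrame (paths relative to
    ``root``) or a dataset directory.  Shuffling is seeded from the config;
    a plain-text loss log and a final checkpoint are written under
    ``out_dir`` when given.  A non-finite loss aborts with diagnostics.
    """
    from .synthetic import load_manifest

    config = config or model.config
    if isinstance(manifest, (str, Path)):
        root = Path(manifest)
        manifest = load_manifest(root)
    if len(manifest) == 0:
        raise ValueError("training dataset is empty")

    x, poses = load_samples(manifest, root)
    spec = CubeSpec(config.half_side, config.grid_size)
    cells, offs = _sparse_targets(poses, spec)
    # head-layout cell indices: (z, image row, x) with row = G-1-y (see forward_raw)
    g = config.grid_size
    cells_zyx = np.stack(
        [cells[:, :, 2], g - 1 - cells[:, :, 1], cells[:, :, 0]], axis=-1
    )

    rng = np.random.default_rng(config.seed + 1)
    opt = _Adam(model.params(), config.learning_rate)
    n = x.shape[0]
    losses: list[float] = []
    log_lines: list[str] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            model.zero_grad()
            y = model._forward_layers(x[idx])
            g = config.grid_size
            raw = y.reshape(len(idx), N_KEYPOINTS, 4, g, g, g)
            batch_loss, grad = _batch_loss_grad(raw, cells_zyx[idx], offs[idx])
            if not np.isfinite(batch_loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {start // config.batch_size}: "
                    f"loss={batch_loss}"
                )
            model._backward_layers(grad.reshape(len(idx), -1, g, g))
            opt.step()
            epoch_loss += batch_loss * len(idx)
        losses.append(epoch_loss / n)
        if epoch % log_every == 0 or epoch == config.epochs - 1:
            log_lines.append(f"epoch {epoch} loss {losses[-1]:.8g}")

    checkpoint = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "train_log.txt").write_text("\n".join(log_lines) + "\n")
        checkpoint = out / "checkpoint.npz"
        model.save(checkpoint)
    return TrainState(epoch=config.epochs, losses=losses, checkpoint=checkpoint)


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------


def infer_sequence(
    model: PoseNet,
    frames: np.ndarray | Sequence[np.ndarray],
    fps: float = 30.0,
    batch_size: int = 16,
) -> tuple[MotionSequence, np.ndarray]:
    """Decode a frame stream to poses with temporal matching.

    A sliding window of three consecutive frames produces one pose per
    window (N frames -> N-2 poses); near-tied hottest cells are resolved
    against the two previously decoded poses.  Returns the decoded sequence
    (timestamps follow the input clock, starting at the third frame) and the
    (N-2, 24) per-keypoint confidences.
    """
    frames = np.asarray(frames)
    if frames.ndim != 4 or frames.shape[0] < 3:
        raise ValueError("need at least 3 frames of shape (side, side, 3)")
    side = model.config.input_side
    if frames.shape[1] != side or frames.shape[2] != side:
        raise ValueError(f"frames must be {side}x{side}, got {frames.shape[1:3]}")
    x = frames.astype(_DTYPE) / 255.0
    windows = np.concatenate(
        [
            x[:-2].transpose(0, 3, 1, 2),
            x[1:-1].transpose(0, 3, 1, 2),
            x[2:].transpose(0, 3, 1, 2),
        ],
        axis=1,
    )
    n_out = windows.shape[0]
    decoded: list[Pose3D] = []
    confs = np.zeros((n_out, N_KEYPOINTS))
    spec = CubeSpec(model.config.half_side, model.config.grid_size)
    for start in range(0, n_out, batch_size):
        vols = model.predict_volumes(windows[start : start + batch_size])
        for i, vol in enumerate(vols):
            t = start + i
            history = [decoded[j] for j in (-1, -2) if len(decoded) >= -j]
            pose, conf = decode(
                vol, spec, history=history, frame_index=t, timestamp=(t + 2) / fps
            )
            decoded.append(pose)
            confs[t] = conf
    return MotionSequence(decoded, fps), confs
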
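"""Dual-pathway patch-based 3D CNN with sparsified-training augmentation.

The architecture follows the two-pathway design popularized by DeepMedic: a
normal-resolution pathway sees a central crop of the input window at full
resolution, and a subsampled pathway sees the whole window mean-pooled by a
downsample factor, giving it a larger physical receptive field for the same
compute.  Both pathways are stacks of valid 3x3x3 convolutions with ReLU;
the subsampled features are upsampled back and concatenated, followed by
1x1x1 ("fully connected") layers and a 2-class voxelwise classifier over the
output patch.

Geometry rule (per axis, kernel k, L conv layers, downsample factor f,
input window S with S divisible by f):

    output      = (S/f - L*(k-1)) * f
    hi-res crop =  output + L*(k-1)

The default preset (S=57, f=3, L=8, k=3) yields the 9x9x9 output patch and,
with its two 1x1x1 hidden layers and the classifier, 11 weighted layers per
pathway chain.

Training minimizes a soft Dice loss with Adam under a stepped learning-rate
schedule and keeps the final-iteration weights (no early stopping, no
validation-based model selection).  Sparsified training is an augmentation
applied to each sampled patch stack after normalization: every secondary
channel is independently replaced by zeros with probability ``sparsify_p``,
so augmented-missing channels reach the network exactly as originally
missing ones do.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import _nn
from .io import CHANNEL_NAMES, SegmentationMask, Subject

__all__ = [
    "NetConfig", "TrainConfig", "DualPathwayNet", "build_network",
    "sparsify_channels", "lr_schedule", "sample_patch", "dice_loss",
    "train", "predict", "save_model", "load_model",
]


@dataclasses.dataclass(frozen=True)
class NetConfig:
    """Architecture hyperparameters; geometry is validated at construction."""

    n_channels: int = 4
    conv_layers_per_pathway: int = 8
    kernel_size: int = 3
    feature_maps: tuple[int, ...] = (30, 30, 40, 40, 40, 40, 50, 50)
    fc_sizes: tuple[int, ...] = (150, 150)
    downsample_factor: int = 3
    input_patch: int = 57
    dtype: str = "float32"

    def __post_init__(self):
        if len(self.feature_maps) != self.conv_layers_per_pathway:
            raise ValueError("feature_maps length must equal conv_layers_per_pathway")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if self.input_patch % self.downsample_factor != 0:
            raise ValueError(
                f"input_patch {self.input_patch} not divisible by "
                f"downsample factor {self.downsample_factor}")
        if self.output_patch <= 0:
            raise ValueError(
                f"invalid geometry: input {self.input_patch}, factor "
                f"{self.downsample_factor}, {self.conv_layers_per_pathway} conv "
                f"layers of kernel {self.kernel_size} give low-res output "
                f"{self.input_patch // self.downsample_factor - self.shrink} <= 0")

    @property
    def shrink(self) -> int:
        """Per-axis size lost by one pathway's stack of valid convolutions."""
        return self.conv_layers_per_pathway * (self.kernel_size - 1)

    @property
    def output_patch(self) -> int:
        return (self.input_patch // self.downsample_factor - self.shrink) \
            * self.downsample_factor

    @property
    def highres_patch(self) -> int:
        return self.output_patch + self.shrink

    @property
    def lowres_patch(self) -> int:
        return self.input_patch // self.downsample_factor

    @property
    def n_weighted_layers(self) -> int:
        return self.conv_layers_per_pathway + len(self.fc_sizes) + 1

    @classmethod
    def full(cls) -> "NetConfig":
        return cls()

    @classmethod
    def tiny(cls) -> "NetConfig":
        """CPU-scale preset obeying the same geometry rule (27^3 -> 9^3)."""
        return cls(conv_layers_per_pathway=3, feature_maps=(8, 8, 16),
                   fc_sizes=(32,), input_patch=27)


@dataclasses.dataclass(frozen=True)
class TrainConfig:
    """Training-loop hyperparameters, including the sparsification rate."""

    iterations: int = 30_000
    lr0: float = 0.001
    lr_step_initial: int = 5000   # halve every this many iterations ...
    lr_step_until: int = 15_000   # ... up to here,
    lr_step_late: int = 1500      # and every this many afterwards
    batch_size: int = 32
    sparsify_p: float = 0.2
    #: "patch": one draw per sampled patch stack (augmentation-layer reading);
    #: "volume": one draw per subject per iteration
    sparsify_scope: str = "patch"
    foreground_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.sparsify_p <= 1.0:
            raise ValueError("sparsify_p must be in [0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.sparsify_scope not in ("patch", "volume"):
            raise ValueError("sparsify_scope must be 'patch' or 'volume'")

    @classmethod
    def full(cls, seed: int = 0) -> "TrainConfig":
        return cls(seed=seed)

    @classmethod
    def tiny(cls, seed: int = 0, iterations: int = 500) -> "TrainConfig":
        # schedule scaled to the shortened run, same shape as the default
        return cls(iterations=iterations, lr_step_initial=150, lr_step_until=300,
                   lr_step_late=75, batch_size=16, seed=seed)


def lr_schedule(iteration: int, config: TrainConfig) -> float:
    """Piecewise-constant stepped learning rate.

    Starts at ``lr0``; halved at every multiple of ``lr_step_initial`` up to
    ``lr_step_until`` and at every further ``lr_step_late`` step beyond that.
    """
    if iteration < 0 or iteration >= config.iterations:
        raise ValueError(f"iteration {iteration} outside [0, {config.iterations})")
    early = min(iteration, config.lr_step_until) // config.lr_step_initial
    late = max(0, iteration - config.lr_step_until) // config.lr_step_late
    return config.lr0 / 2.0 ** (early + late)


def sparsify_channels(patches, p: float, rng: np.random.Generator, drop=None):
    """Randomly zero secondary channels of a patch stack (channel axis 0).

    ``patches`` is either a single ``(C, ...)`` array or a sequence of such
    arrays sharing the channel axis (e.g. matched high-res and low-res
    stacks); one draw per secondary channel is applied to all of them, so a
    channel is dropped consistently across resolutions.  The primary channel
    (index 0) is never zeroed.  Idempotent on already-zero channels.
    ``drop`` supplies a precomputed boolean mask over the secondary channels
    (used for per-volume sparsification scope).
    """
    single = isinstance(patches, np.ndarray)
    stacks = [patches] if single else list(patches)
    n_ch = stacks[0].shape[0]
    if drop is None:
        drop = rng.random(n_ch - 1) < p
    out = []
    for s in stacks:
        s = s.copy()
        for c in range(1, n_ch):
            if drop[c - 1]:
                s[c] = 0.0
        out.append(s)
    return out[0] if single else tuple(out)


def dice_loss(probs: np.ndarray, labels: np.ndarray, eps: float = 1e-5) -> float:
    """Batch-averaged soft Dice loss on the foreground class.

    ``probs`` is ``(N, 2, d, h, w)`` class probabilities (class 1 =
    foreground), ``labels`` is ``(N, d, h, w)`` binary ground truth.
    """
    loss, _ = _nn.soft_dice_loss(np.moveaxis(probs, 1, -1), labels, eps)
    return loss


class DualPathwayNet:
    """Two convolutional pathways with shared topology and separate weights."""

    def __init__(self, config: NetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        dt = np.dtype(config.dtype).type
        k = config.kernel_size

        def pathway():
            layers = []
            c_in = config.n_channels
            for li, f in enumerate(config.feature_maps):
                layers.append(_nn.Conv3d(c_in, f, k, rng, dtype=dt,
                                         needs_input_grad=li > 0))
                layers.append(_nn.ReLU())
                c_in = f
            return layers, c_in

        self.hi_path, hi_out = pathway()
        self.lo_path, lo_out = pathway()
        self.fc_layers = []
        c_in = hi_out + lo_out
        for f in config.fc_sizes:
            self.fc_layers.append(_nn.Conv3d(c_in, f, 1, rng, dtype=dt))
            self.fc_layers.append(_nn.ReLU())
            c_in = f
        self.classifier = _nn.Conv3d(c_in, 2, 1, rng, dtype=dt)
        self._geometry_self_check()

    def _geometry_self_check(self) -> None:
        cfg = self.config
        expect = cfg.highres_patch - cfg.shrink
        if expect != cfg.output_patch:
            raise AssertionError(
                f"pathway output {expect} != derived output patch {cfg.output_patch}")
        lo_expect = (cfg.lowres_patch - cfg.shrink) * cfg.downsample_factor
        if lo_expect != cfg.output_patch:
            raise AssertionError(
                f"upsampled low-res output {lo_expect} != {cfg.output_patch}")

    @property
    def layers(self):
        return self.hi_path + self.lo_path + self.fc_layers + [self.classifier]

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers if hasattr(l, "n_params"))

    # internal compute is channels-last (N, d, h, w, C)
    def _forward(self, hi_cl: np.ndarray, lo_cl: np.ndarray) -> np.ndarray:
        x = hi_cl
        for layer in self.hi_path:
            x = layer.forward(x)
        z = lo_cl
        for layer in self.lo_path:
            z = layer.forward(z)
        z = _nn.upsample_nearest3d(z, self.config.downsample_factor)
        self._split = x.shape[-1]
        y = np.concatenate([x, z], axis=-1)
        for layer in self.fc_layers:
            y = layer.forward(y)
        return self.classifier.forward(y)

    def _backward(self, dlogits_cl: np.ndarray) -> None:
        g = self.classifier.backward(dlogits_cl)
        for layer in reversed(self.fc_layers):
            g = layer.backward(g)
        g_hi = np.ascontiguousarray(g[..., :self._split])
        g_lo = _nn.upsample_nearest3d_backward(
            np.ascontiguousarray(g[..., self._split:]), self.config.downsample_factor)
        for layer in reversed(self.hi_path):
            g_hi = layer.backward(g_hi)
        for layer in reversed(self.lo_path):
            g_lo = layer.backward(g_lo)

    def forward(self, hi: np.ndarray, lo: np.ndarray) -> np.ndarray:
        """(N, C, hi^3) and (N, C, lo^3) stacks -> (N, 2, out^3) logits."""
        logits = self._forward(np.ascontiguousarray(np.moveaxis(hi, 1, -1)),
                               np.ascontiguousarray(np.moveaxis(lo, 1, -1)))
        return np.moveaxis(logits, -1, 1)

    def backward(self, dlogits: np.ndarray) -> None:
        self._backward(np.ascontiguousarray(np.moveaxis(dlogits, 1, -1)))

    def predict_proba(self, hi: np.ndarray, lo: np.ndarray) -> np.ndarray:
        return _nn.softmax(self.forward(hi, lo), axis=1)

    # -- serialization ----------------------------------------------------
    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers):
            if hasattr(layer, "w"):
                state[f"w{i}"] = layer.w
                state[f"b{i}"] = layer.b
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            if hasattr(layer, "w"):
                layer.w = np.array(state[f"w{i}"], dtype=layer.w.dtype)
                layer.b = np.array(state[f"b{i}"], dtype=layer.b.dtype)


def build_network(config: NetConfig, seed: int = 0) -> DualPathwayNet:
    """Construct the dual-pathway network; invalid geometry fails here."""
    return DualPathwayNet(config, seed=seed)


def save_model(model: DualPathwayNet, path) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **model.state_dict())
    path.with_suffix(".json").write_text(
        json.dumps(dataclasses.asdict(model.config), indent=2))


def load_model(path) -> DualPathwayNet:
    path = Path(path)
    cfg = json.loads(path.with_suffix(".json").read_text())
    cfg["feature_maps"] = tuple(cfg["feature_maps"])
    cfg["fc_sizes"] = tuple(cfg["fc_sizes"])
    model = DualPathwayNet(NetConfig(**cfg), seed=0)
    with np.load(path.with_suffix(".npz")) as state:
        model.load_state_dict(dict(state))
    return model


# -- patch sampling -------------------------------------------------------

def _pad_stack(subject: Subject, margin: int) -> np.ndarray:
    pad = ((0, 0),) + ((margin, margin),) * 3
    return np.pad(subject.channels, pad)


def _pool_cf(stack: np.ndarray, f: int) -> np.ndarray:
    """Mean-pool a channels-first (C, D, H, W) stack by factor f."""
    c, d, h, w = stack.shape
    return stack.reshape(c, d // f, f, h // f, f, w // f, f).mean(axis=(2, 4, 6))


def sample_patch(subject: Subject, rng: np.random.Generator,
                 net_config: NetConfig, foreground_fraction: float = 0.5,
                 padded: Optional[np.ndarray] = None,
                 fg_idx: Optional[np.ndarray] = None,
                 bg_idx: Optional[np.ndarray] = None):
    """Draw one training patch triple from a normalized subject.

    Returns ``(hi, lo, label)``: the high-res central crop, the mean-pooled
    full window, and the central output-patch of the ground-truth mask.  The
    center voxel lies in the tumor core with probability
    ``foreground_fraction`` (falling back to brain voxels when the mask is
    empty), else uniformly in the brain mask.  Context outside the volume is
    zero-padded.  ``padded``/``fg_idx``/``bg_idx`` allow a caller to reuse
    precomputed state across draws.
    """
    cfg = net_config
    S = cfg.input_patch
    margin = S // 2
    if padded is None:
        padded = _pad_stack(subject, margin)
    if fg_idx is None:
        fg_idx = np.argwhere(subject.mask > 0) if subject.mask is not None \
            else np.empty((0, 3), dtype=int)
    if bg_idx is None:
        bg_idx = np.argwhere(subject.brain_mask > 0)

    want_fg = rng.random() < foreground_fraction
    if want_fg and len(fg_idx) == 0 and subject.mask is not None:
        logging.getLogger(__name__).warning(
            "subject %s: empty mask, foreground sample falls back to background",
            subject.subject_id)
    use_fg = want_fg and len(fg_idx) > 0
    pool = fg_idx if use_fg else bg_idx
    center = pool[rng.integers(len(pool))]

    window = padded[:, center[0]:center[0] + S, center[1]:center[1] + S,
                    center[2]:center[2] + S]
    lo = _pool_cf(window, cfg.downsample_factor)
    off = (S - cfg.highres_patch) // 2
    hi = window[:, off:off + cfg.highres_patch, off:off + cfg.highres_patch,
                off:off + cfg.highres_patch].copy()

    o = cfg.output_patch
    loff = (S - o) // 2 - margin  # offset back in unpadded coordinates
    starts = center + loff
    label = np.zeros((o, o, o), dtype=np.uint8)
    if subject.mask is not None:
        src_lo = np.maximum(starts, 0)
        src_hi = np.minimum(starts + o, subject.mask.shape)
        dst_lo = src_lo - starts
        dst_hi = dst_lo + (src_hi - src_lo)
        if np.all(src_hi > src_lo):
            label[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = \
                subject.mask[src_lo[0]:src_hi[0], src_lo[1]:src_hi[1],
                             src_lo[2]:src_hi[2]]
    return hi, lo, label


# -- training -------------------------------------------------------------

def train(subjects: Sequence[Subject], net_config: NetConfig,
          train_config: TrainConfig, sparsified: bool = False):
    """Train on normalized subjects; returns ``(model, log)``.

    The final-iteration weights are the deliverable.  The log is a DataFrame
    with one row per iteration (loss, learning rate).  With ``sparsified``,
    each sampled patch stack has its secondary channels independently zeroed
    with probability ``train_config.sparsify_p`` — after normalization, so
    augmented zeros are indistinguishable from originally-missing channels.
    Sparsification uses a dedicated random stream, so a seed-matched pair of
    runs differing only in this flag shares initialization and patch order.
    """
    if not subjects:
        raise ValueError("no training subjects")
    for s in subjects:
        if s.mask is None:
            raise ValueError(f"subject {s.subject_id} has no ground-truth mask")

    cfg, tc = net_config, train_config
    model = DualPathwayNet(cfg, seed=tc.seed)
    opt = _nn.Adam(model.layers)
    sample_rng = np.random.default_rng([tc.seed, 1])
    sparsify_rng = np.random.default_rng([tc.seed, 2])

    margin = cfg.input_patch // 2
    padded = [_pad_stack(s, margin) for s in subjects]
    fg = [np.argwhere(s.mask > 0) for s in subjects]
    bg = [np.argwhere(s.brain_mask > 0) for s in subjects]

    rows = []
    dt = np.dtype(cfg.dtype).type
    n_secondary = len(CHANNEL_NAMES) - 1
    for it in range(tc.iterations):
        his, los, labels = [], [], []
        volume_drops: dict[int, np.ndarray] = {}
        for _ in range(tc.batch_size):
            si = int(sample_rng.integers(len(subjects)))
            hi, lo, lab = sample_patch(subjects[si], sample_rng, cfg,
                                       tc.foreground_fraction,
                                       padded=padded[si], fg_idx=fg[si],
                                       bg_idx=bg[si])
            if sparsified:
                drop = None
                if tc.sparsify_scope == "volume":
                    if si not in volume_drops:
                        volume_drops[si] = sparsify_rng.random(n_secondary) \
                            < tc.sparsify_p
                    drop = volume_drops[si]
                hi, lo = sparsify_channels((hi, lo), tc.sparsify_p, sparsify_rng,
                                           drop=drop)
            his.append(hi)
            los.append(lo)
            labels.append(lab)
        # channels-last batches for the compute core
        hi_b = np.ascontiguousarray(np.stack(his).transpose(0, 2, 3, 4, 1)).astype(dt)
        lo_b = np.ascontiguousarray(np.stack(los).transpose(0, 2, 3, 4, 1)).astype(dt)
        lab_b = np.stack(labels)

        logits = model._forward(hi_b, lo_b)
        probs = _nn.softmax(logits, axis=-1)
        loss, dprobs = _nn.soft_dice_loss(probs, lab_b)
        if not np.isfinite(loss):
            raise RuntimeError(
                f"non-finite loss {loss} at iteration {it}; "
                f"lr={lr_schedule(it, tc)}, check normalization and inputs")
        # softmax backward: dz_i = p_i * (g_i - sum_j g_j p_j)
        dot = (dprobs * probs).sum(axis=-1, keepdims=True)
        dlogits = probs * (dprobs - dot)
        model._backward(dlogits.astype(dt))
        lr = lr_schedule(it, tc)
        opt.step(lr)
        rows.append((it, lr, loss))

    log = pd.DataFrame(rows, columns=["iteration", "lr", "loss"])
    return model, log


# -- whole-volume inference ------------------------------------------------

def predict(model: DualPathwayNet, subject: Subject,
            tile_batch: int = 32) -> SegmentationMask:
    """Tile a normalized subject with stride = output patch and argmax.

    The volume is conceptually padded to a multiple of the output patch so
    every voxel is predicted exactly once; borders see zero-padded context.
    """
    cfg = model.config
    S, o = cfg.input_patch, cfg.output_patch
    shape = np.array(subject.shape)
    n_tiles = -(-shape // o)  # ceil
    ext = n_tiles * o
    ctx = (S - o) // 2
    pad = [(0, 0)] + [(ctx, ctx + int(e - d)) for e, d in zip(ext, shape)]
    padded = np.pad(subject.channels, pad)

    starts = [(i * o, j * o, k * o)
              for i in range(n_tiles[0]) for j in range(n_tiles[1])
              for k in range(n_tiles[2])]
    out = np.zeros(tuple(ext), dtype=np.uint8)
    dt = np.dtype(cfg.dtype).type
    off = (S - cfg.highres_patch) // 2
    for b0 in range(0, len(starts), tile_batch):
        batch = starts[b0:b0 + tile_batch]
        his, los = [], []
        for (z, y, x) in batch:
            window = padded[:, z:z + S, y:y + S, x:x + S]
            los.append(_pool_cf(window, cfg.downsample_factor))
            his.append(window[:, off:off + cfg.highres_patch,
                              off:off + cfg.highres_patch,
                              off:off + cfg.highres_patch])
        hi_b = np.ascontiguousarray(np.stack(his).transpose(0, 2, 3, 4, 1)).astype(dt)
        lo_b = np.ascontiguousarray(np.stack(los).transpose(0, 2, 3, 4, 1)).astype(dt)
        logits = model._forward(hi_b, lo_b)
        pred = np.argmax(logits, axis=-1).astype(np.uint8)
        for t, (z, y, x) in enumerate(batch):
            out[z:z + o, y:y + o, x:x + o] = pred[t]
    out = out[:shape[0], :shape[1], :shape[2]]
    return SegmentationMask(voxels=out, spacing=subject.spacing)
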
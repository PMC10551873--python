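"""U-Net segmentation of rod micromotors.

The network maps a grayscale frame to a per-pixel heatmap in [0, 1]
marking micromotor pixels while suppressing bubbles and illumination.
Architecture: ``depth`` encoder levels of two 3x3 conv + ReLU layers
(``base_filters * 2**i`` channels at level i) separated by 2x2 max
pooling; a decoder of 2x2-stride-2 transposed convolutions, each
followed by concatenation with the matching encoder feature map and two
conv + ReLU layers; a two-conv head reducing to one channel; sigmoid
output.  Same-padded convolutions keep the output the size of the
input.  Training minimizes pixelwise binary cross-entropy with AMSgrad.

Frames are min-max normalized to [0, 1] per frame before entering the
network, both in training and inference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import nn
from .config import TrainConfig, UNetSpec

__all__ = [
    "UNet",
    "TrainingHistory",
    "build_model",
    "train",
    "predict",
    "dice_coefficient",
    "save_checkpoint",
    "load_checkpoint",
]


def _normalize(frame: np.ndarray) -> np.ndarray:
    """Standardize a frame to zero mean, unit variance.

    Centering removes the (arbitrary) illumination level and unit
    variance keeps activation magnitudes -- and therefore gradient
    signal per optimizer step -- independent of the camera's contrast
    scale.  Constant frames map to zeros.
    """
    f = np.asarray(frame, dtype=np.float32)
    sd = float(f.std())
    if sd == 0.0:
        return np.zeros_like(f)
    return (f - float(f.mean())) / sd


class UNet:
    """The network; holds layers and runs explicit forward/backward."""

    def __init__(self, spec: UNetSpec, seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        d, f = spec.depth, spec.base_filters

        def block(c_in, c_out):
            return [nn.Conv2d(c_in, c_out, rng=rng, dtype=dtype), nn.ReLU(),
                    nn.Conv2d(c_out, c_out, rng=rng, dtype=dtype), nn.ReLU()]

        self.enc = []
        c_prev = spec.in_channels
        for i in range(d):
            c = f * 2 ** i
            self.enc.append(block(c_prev, c))
            c_prev = c
        self.pools = [nn.MaxPool2d() for _ in range(d - 1)]
        self.ups, self.dec = [], []
        for i in range(d - 2, -1, -1):
            c = f * 2 ** i
            self.ups.append(nn.ConvTranspose2d(2 * c, c, rng=rng, dtype=dtype))
            self.dec.append(block(2 * c, c))
        self.head = [nn.Conv2d(f, f, rng=rng, dtype=dtype), nn.ReLU(),
                     nn.Conv2d(f, spec.out_channels, rng=rng, dtype=dtype)]
        p = spec.foreground_prior
        self.head[-1].b.value[:] = np.log(p / (1.0 - p))

    # -- parameter access -------------------------------------------------
    def _layers(self):
        for blk in self.enc:
            yield from blk
        yield from self.pools
        for up, blk in zip(self.ups, self.dec):
            yield up
            yield from blk
        yield from self.head

    def params(self) -> list[nn.Param]:
        out = []
        for layer in self._layers():
            out.extend(layer.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    # -- forward / backward ------------------------------------------------
    def _check_dims(self, h: int, w: int) -> None:
        m = 2 ** (self.spec.depth - 1)
        if h % m or w % m:
            raise ValueError(
                f"input dims {h}x{w} must be divisible by {m} "
                f"(2**(depth-1) for depth {self.spec.depth}); pad or crop the "
                f"frames, or lower the depth")

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """x: (N, 1, H, W) -> logits (N, 1, H, W)."""
        self._check_dims(x.shape[2], x.shape[3])
        d = self.spec.depth
        skips = []
        h = x.astype(self.dtype, copy=False)
        for i in range(d):
            for layer in self.enc[i]:
                h = layer.forward(h)
            if i < d - 1:
                skips.append(h)
                h = self.pools[i].forward(h)
        self._split = []
        for j, i in enumerate(range(d - 2, -1, -1)):
            h = self.ups[j].forward(h)
            h = np.concatenate([h, skips[i]], axis=1)
            self._split.append(h.shape[1] // 2)
            for layer in self.dec[j]:
                h = layer.forward(h)
        for layer in self.head:
            h = layer.forward(h)
        return h

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.spec.depth
        g = dlogits
        for layer in reversed(self.head):
            g = layer.backward(g)
        dskips = {}
        for j in range(d - 2, -1, -1):
            i = d - 2 - j
            for layer in reversed(self.dec[j]):
                g = layer.backward(g)
            c = self._split[j]
            dskips[i] = g[:, c:]
            g = self.ups[j].backward(np.ascontiguousarray(g[:, :c]))
        for i in range(d - 1, -1, -1):
            for layer in reversed(self.enc[i]):
                g = layer.backward(g)
            if i > 0:
                g = self.pools[i - 1].backward(g)
                g = g + dskips[i - 1]

    def predict_heatmaps(self, frames: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """frames: (N, H, W), already normalized -> heatmaps (N, H, W)."""
        out = np.empty(frames.shape, dtype=np.float32)
        for s in range(0, len(frames), batch_size):
            batch = frames[s:s + batch_size][:, None]
            out[s:s + batch_size] = nn.sigmoid(self.forward_logits(batch))[:, 0]
        return out


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)


def build_model(spec: UNetSpec, seed: int = 0) -> UNet:
    """Construct a seeded, He-initialized U-Net."""
    return UNet(spec, seed=seed)


def dice_coefficient(pred: np.ndarray, target: np.ndarray,
                     threshold: float = 0.5) -> float:
    """Dice overlap 2|A^B| / (|A| + |B|) of the thresholded prediction.

    Defined as 1.0 when both masks are empty.
    """
    a = np.asarray(pred) >= threshold
    b = np.asarray(target) > 0
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


def _as_arrays(dataset) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dataset, tuple) and len(dataset) == 2:
        frames, masks = dataset
    else:
        pairs = list(dataset)
        if not pairs:
            raise ValueError("dataset is empty")
        for i, (f, m) in enumerate(pairs):
            if np.shape(f) != np.shape(m):
                raise ValueError(f"pair {i}: frame shape {np.shape(f)} != "
                                 f"mask shape {np.shape(m)}")
        frames = np.stack([p[0] for p in pairs])
        masks = np.stack([p[1] for p in pairs])
    frames = np.asarray(frames)
    masks = np.asarray(masks)
    if frames.shape[0] == 0:
        raise ValueError("dataset is empty")
    if frames.shape != masks.shape:
        for i, (f, m) in enumerate(zip(frames, masks)):
            if f.shape != m.shape:
                raise ValueError(
                    f"pair {i}: frame shape {f.shape} != mask shape {m.shape}")
        raise ValueError(
            f"frames {frames.shape} and masks {masks.shape} are misaligned")
    uniq = np.unique(masks)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError(f"masks must be binary, found values {uniq[:10]}")
    return frames, masks


def train(model: UNet, dataset, config: TrainConfig) -> tuple[UNet, TrainingHistory]:
    """Fit the model by mini-batch AMSgrad on binary cross-entropy.

    ``dataset`` is either an ``(frames, masks)`` array pair or an
    iterable of (frame, mask) pairs.  Shuffling, the train/validation
    split (last ``validation_fraction`` of the shuffled data) and all
    updates are driven by ``config.seed``; repeated runs are identical.
    """
    frames, masks = _as_arrays(dataset)
    n = len(frames)
    x = np.stack([_normalize(f) for f in frames])[:, None]
    y = masks.astype(np.float32)[:, None]

    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n)
    n_val = int(round(n * config.validation_fraction))
    if n_val >= n:
        n_val = n - 1
    train_idx, val_idx = perm[:n - n_val], perm[n - n_val:]

    opt = nn.AMSgrad(model.params(), lr=config.learning_rate)
    history = TrainingHistory()
    for _epoch in range(config.epochs):
        order = train_idx[rng.permutation(len(train_idx))]
        losses = []
        for s in range(0, len(order), config.batch_size):
            idx = order[s:s + config.batch_size]
            logits = model.forward_logits(x[idx])
            loss, dlogits = nn.bce_with_logits(logits, y[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
        history.train_loss.append(float(np.mean(losses)))
        if len(val_idx):
            vloss, vdice = _evaluate(model, x[val_idx], y[val_idx],
                                     config.batch_size)
        else:
            vloss, vdice = float("nan"), float("nan")
        history.val_loss.append(vloss)
        history.val_dice.append(vdice)
    return model, history


def _evaluate(model: UNet, x: np.ndarray, y: np.ndarray,
              batch_size: int) -> tuple[float, float]:
    losses, dices = [], []
    for s in range(0, len(x), batch_size):
        logits = model.forward_logits(x[s:s + batch_size])
        loss, _ = nn.bce_with_logits(logits, y[s:s + batch_size])
        losses.append(loss)
        hm = nn.sigmoid(logits)
        for j in range(len(hm)):
            dices.append(dice_coefficient(hm[j, 0], y[s + j, 0]))
    return float(np.mean(losses)), float(np.mean(dices))


def predict(model: UNet, frames: Sequence[np.ndarray],
            batch_size: int = 8) -> list[np.ndarray]:
    """Run the network over frames (each min-max normalized first).

    Output order matches input order and is independent of how the
    frames are partitioned into batches.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("no frames to segment")
    shape = frames[0].shape
    for i, f in enumerate(frames):
        if f.shape != shape:
            raise ValueError(f"frame {i} shape {f.shape} != {shape}")
    stack = np.stack([_normalize(f) for f in frames])
    heat = model.predict_heatmaps(stack, batch_size=batch_size)
    return [heat[i] for i in range(len(frames))]


# ------------------------------------------------------------- checkpoints

def save_checkpoint(model: UNet, path: str | Path,
                    train_config: Optional[TrainConfig] = None) -> None:
    """Serialize weights with the architecture (and optionally the
    training settings) embedded, so the file is self-describing."""
    meta = {"spec": asdict(model.spec)}
    if train_config is not None:
        meta["train"] = asdict(train_config)
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    # write through a handle so numpy cannot append ".npz" to the name
    with open(path, "wb") as fh:
        np.savez(fh, meta=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> UNet:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["meta"]))
        model = UNet(UNetSpec(**meta["spec"]))
        params = model.params()
        for i, p in enumerate(params):
            saved = data[f"param_{i}"]
            if saved.shape != p.value.shape:
                raise ValueError(
                    f"checkpoint param {i} shape {saved.shape} does not match "
                    f"architecture {p.value.shape}")
            p.value[...] = saved
    return model
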
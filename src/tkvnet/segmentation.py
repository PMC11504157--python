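"""2D U-Net segmentation: model, Dice loss, schedule, training, inference.

The network follows the classic encoder--decoder U shape: repeated
3x3 convolution + ReLU pairs with 2x2 max-pooling on the contracting path,
2x2 transposed-convolution upsampling with skip concatenation on the
expansive path, dropout once at the deepest encoder output, and a final
1x1 convolution with sigmoid producing a per-pixel kidney probability.
All convolutions use "same" padding so spatial size is preserved, and all
weights use He initialization.  Training minimizes a soft Dice loss with
Adam under a warm-up exponential-decay learning-rate schedule, drawing a
fresh set of augmented images every epoch and early-stopping on validation
Dice.

The whole stack — forward, backward, optimizer — is implemented directly
on NumPy arrays (layout ``(N, C, H, W)``, float32).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .dataset import AugmentationParams, LabeledPair, augment_pair
from .geometry_io import SliceStack, prepare_for_model, resample_probabilities

__all__ = [
    "UNetConfig", "TrainConfig", "TrainHistory", "LRSchedule",
    "build_unet", "dice_loss", "lr_at_step", "train", "predict",
    "predict_stack", "save_checkpoint", "load_checkpoint",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyperparameters.

    ``depth`` counts down-sampling stages; channel width doubles each stage
    from ``base_filters``.  Padding is always "same", hidden activations
    ReLU, the head sigmoid, weights He-initialized — these are fixed, not
    configurable.
    """

    depth: int = 4
    base_filters: int = 32
    dropout_rate: float = 0.2
    input_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.input_size // (2 ** self.depth) < 1:
            raise ValueError(
                f"depth {self.depth} collapses a {self.input_size} grid below 1 px")


@dataclass(frozen=True)
class LRSchedule:
    """Warm-up exponential decay: linear ramp to the peak, then geometric decay.

    ``lr(step) = floor + (peak - floor) * step / warmup``   for step < warmup,
    ``lr(step) = peak * decay_rate ** ((step - warmup) / decay_steps)`` after;
    the two branches agree at ``step == warmup``.
    """

    warmup_steps: int = 100
    peak_lr: float = 1e-3
    decay_rate: float = 0.9
    decay_steps: int = 100
    floor: float = 0.0


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 10
    max_epochs: int = 500
    patience: int = 20
    min_delta: float = 1e-4
    lr_schedule: LRSchedule | None = None  # None -> built from epoch length
    warmup_epochs: int = 5
    decay_rate_per_epoch: float = 0.9
    peak_lr: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be >= 1")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_dsc: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    stopped_epoch: int = 0
    best_epoch: int = 0
    best_val_dsc: float = 0.0


def small_data_train_config(max_epochs: int = 50, seed: int = 0) -> TrainConfig:
    """Training configuration for few-slice datasets (tens of images).

    The package defaults (peak 1e-3, decay 0.9 per epoch) suit epochs of
    ~100 optimizer steps; with only one or two steps per epoch they decay
    the learning rate long before convergence.  This variant raises the
    peak to 3e-3 and flattens the decay to 0.99 per epoch, with early
    stopping disabled (patience = max_epochs) since validation Dice on a
    handful of slices is noisy.
    """
    return TrainConfig(batch_size=10, max_epochs=max_epochs, patience=max_epochs,
                       peak_lr=3e-3, decay_rate_per_epoch=0.99,
                       warmup_epochs=5, seed=seed)


def lr_at_step(step: int, schedule: LRSchedule) -> float:
    """Learning rate at a (0-based) optimizer step."""
    if step < schedule.warmup_steps:
        frac = step / max(schedule.warmup_steps, 1)
        return schedule.floor + (schedule.peak_lr - schedule.floor) * frac
    return schedule.peak_lr * schedule.decay_rate ** (
        (step - schedule.warmup_steps) / schedule.decay_steps)


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

def _he_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, H, W, C*9) patches for a same-padded 3x3 conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n, h, w, c * 9)


class _Conv3x3:
    """3x3 convolution, padding same, optional fused ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 relu: bool = True) -> None:
        self.c_in, self.c_out, self.relu = c_in, c_out, relu
        self.W = _he_init(rng, c_in * 9, (c_out, c_in * 9))
        self.b = np.zeros(c_out, dtype=np.float32)

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        n, _, h, w = x.shape
        cols = _im2col3(x)
        out = cols.reshape(-1, self.c_in * 9) @ self.W.T + self.b
        out = out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)
        if self.relu:
            out = np.maximum(out, 0.0)
        self._cols, self._out = cols, out
        return out

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        if self.relu:
            dout = dout * (self._out > 0)
        n, _, h, w = dout.shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        dW = (dflat.T @ self._cols.reshape(-1, self.c_in * 9)).astype(np.float32)
        db = dflat.sum(axis=0).astype(np.float32)
        # dx is the "full" correlation of dout with the flipped kernel
        w3 = self.W.reshape(self.c_out, self.c_in, 3, 3)
        wback = w3[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(
            self.c_in, self.c_out * 9)
        dcols = _im2col3(dout)
        dx = (dcols.reshape(-1, self.c_out * 9) @ wback.T).reshape(
            n, h, w, self.c_in).transpose(0, 3, 1, 2)
        self._cols = self._out = None
        return dx.astype(np.float32), [dW, db]


class _Conv1x1:
    """1x1 convolution head (no activation; sigmoid applied by the model)."""

    def __init__(self, c_in: int, rng: np.random.Generator) -> None:
        self.c_in = c_in
        self.W = _he_init(rng, c_in, (1, c_in))
        self.b = np.zeros(1, dtype=np.float32)

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        return np.einsum("nchw,oc->nohw", x, self.W) + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        dW = np.einsum("nohw,nchw->oc", dout, self._x).astype(np.float32)
        db = dout.sum(axis=(0, 2, 3)).astype(np.float32)
        dx = np.einsum("nohw,oc->nchw", dout, self.W).astype(np.float32)
        self._x = None
        return dx, [dW, db]


class _MaxPool2:
    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        self._arg = r.argmax(axis=-1)
        self._shape = x.shape
        return r.max(axis=-1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        scat = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(scat, self._arg[..., None], dout[..., None], axis=-1)
        dx = scat.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dx.reshape(n, c, h, w)


class _UpConv2:
    """2x2 stride-2 transposed convolution (learned upsampling)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        self.c_in, self.c_out = c_in, c_out
        self.W = _he_init(rng, c_in * 4, (c_in, c_out, 2, 2))
        self.b = np.zeros(c_out, dtype=np.float32)

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        self._x = x
        n, _, h, w = x.shape
        out = np.einsum("ncij,cdab->ndiajb", x, self.W)
        return out.reshape(n, self.c_out, 2 * h, 2 * w) + self.b[None, :, None, None]

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        n, _, h2, w2 = dout.shape
        d6 = dout.reshape(n, self.c_out, h2 // 2, 2, w2 // 2, 2).transpose(
            0, 1, 2, 4, 3, 5)  # n, d, i, j, a, b
        dW = np.einsum("ncij,ndijab->cdab", self._x, d6).astype(np.float32)
        db = dout.sum(axis=(0, 2, 3)).astype(np.float32)
        dx = np.einsum("ndijab,cdab->ncij", d6, self.W).astype(np.float32)
        self._x = None
        return dx, [dW, db]


class _Dropout:
    def __init__(self, rate: float) -> None:
        self.rate = rate

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator) -> np.ndarray:
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return (x * self._mask).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return (dout * self._mask).astype(np.float32)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class UNet:
    """The assembled network; use :func:`build_unet` to construct one."""

    def __init__(self, cfg: UNetConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self._dropout_rng = np.random.default_rng(cfg.seed + 1)
        ch = [cfg.base_filters * 2 ** i for i in range(cfg.depth + 1)]

        self.enc: list[tuple[_Conv3x3, _Conv3x3]] = []
        c_prev = 1
        for i in range(cfg.depth):
            self.enc.append((_Conv3x3(c_prev, ch[i], rng), _Conv3x3(ch[i], ch[i], rng)))
            c_prev = ch[i]
        self.pools = [_MaxPool2() for _ in range(cfg.depth)]
        self.bott = (_Conv3x3(c_prev, ch[cfg.depth], rng),
                     _Conv3x3(ch[cfg.depth], ch[cfg.depth], rng))
        self.drop = _Dropout(cfg.dropout_rate)
        self.ups: list[_UpConv2] = []
        self.dec: list[tuple[_Conv3x3, _Conv3x3]] = []
        for i in range(cfg.depth - 1, -1, -1):
            self.ups.append(_UpConv2(ch[i + 1], ch[i], rng))
            self.dec.append((_Conv3x3(2 * ch[i], ch[i], rng), _Conv3x3(ch[i], ch[i], rng)))
        self.head = _Conv1x1(ch[0], rng)

    # -- parameter plumbing -------------------------------------------------
    def _layers_with_params(self):
        out = []
        for a, b in self.enc:
            out += [a, b]
        out += [self.bott[0], self.bott[1]]
        for up, (a, b) in zip(self.ups, self.dec):
            out += [up, a, b]
        out.append(self.head)
        return out

    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self._layers_with_params() for p in layer.params()]

    def set_parameters(self, params: list[np.ndarray]) -> None:
        own = self.parameters()
        if len(own) != len(params):
            raise ValueError("parameter list length mismatch")
        for dst, src in zip(own, params):
            if dst.shape != src.shape:
                raise ValueError("parameter shape mismatch")
            dst[...] = src

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        """Input (N, 1, H, W) in [0, 1] -> sigmoid probabilities, same shape."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError("expected input of shape (N, 1, H, W)")
        h = x
        self._skips = []
        for (c1, c2), pool in zip(self.enc, self.pools):
            h = c2.forward(c1.forward(h, training), training)
            self._skips.append(h)
            h = pool.forward(h)
        h = self.bott[1].forward(self.bott[0].forward(h, training), training)
        h = self.drop.forward(h, training, self._dropout_rng)
        for up, (c1, c2) in zip(self.ups, self.dec):
            h = up.forward(h, training)
            skip = self._skips.pop()
            h = np.concatenate([skip, h], axis=1)
            h = c2.forward(c1.forward(h, training), training)
        logits = self.head.forward(h, training)
        self._probs = 1.0 / (1.0 + np.exp(-np.clip(logits, -60.0, 60.0)))
        return self._probs

    def backward(self, dprobs: np.ndarray) -> list[np.ndarray]:
        """Backpropagate dL/dprobs; returns gradients aligned with parameters()."""
        grads_rev: list[np.ndarray] = []
        d = (dprobs * self._probs * (1.0 - self._probs)).astype(np.float32)
        d, g = self.head.backward(d)
        grads_rev += g[::-1]
        skip_grads: list[np.ndarray] = []
        ch = [self.cfg.base_filters * 2 ** i for i in range(self.cfg.depth)]
        # walk the decoder in reverse build order; ups/dec were built from the
        # deepest level outward, so reversed they run level 0 -> depth-1
        for up, (c1, c2), c_skip in zip(self.ups[::-1], self.dec[::-1], ch):
            d, g2 = c2.backward(d)
            grads_rev += g2[::-1]
            d, g1 = c1.backward(d)
            grads_rev += g1[::-1]
            d_skip, d_up = d[:, :c_skip], d[:, c_skip:]
            skip_grads.append(d_skip)
            d, gu = up.backward(d_up)
            grads_rev += gu[::-1]
        d = self.drop.backward(d)
        d, gb2 = self.bott[1].backward(d)
        grads_rev += gb2[::-1]
        d, gb1 = self.bott[0].backward(d)
        grads_rev += gb1[::-1]
        # skip_grads were collected shallow-first; encoder walks deepest-first
        for pool, (c1, c2) in zip(self.pools[::-1], self.enc[::-1]):
            d = pool.backward(d)
            d = d + skip_grads.pop()
            d, g2 = c2.backward(d)
            grads_rev += g2[::-1]
            d, g1 = c1.backward(d)
            grads_rev += g1[::-1]
        return grads_rev[::-1]


def build_unet(cfg: UNetConfig) -> UNet:
    """Construct a U-Net for ``cfg.input_size`` square inputs."""
    return UNet(cfg)


# ---------------------------------------------------------------------------
# Loss and metric
# ---------------------------------------------------------------------------

def dice_loss(pred: np.ndarray, truth: np.ndarray, eps: float = 1e-6) -> float:
    """Soft Dice loss ``1 - (2*sum(p*t)+eps) / (sum(p)+sum(t)+eps)``.

    ``pred`` holds probabilities, ``truth`` is binary; sums pool over the
    whole arrays.  Differentiable in ``pred``.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if not np.all(np.isin(np.unique(truth), (0, 1))):
        raise ValueError("truth must be binary")
    num = 2.0 * float((pred * truth).sum()) + eps
    den = float(pred.sum()) + float(truth.sum()) + eps
    return 1.0 - num / den


def _soft_dice_batch(probs: np.ndarray, truth: np.ndarray,
                     eps: float = 1e-6) -> tuple[float, np.ndarray]:
    """Per-sample soft Dice loss averaged over the batch, with its gradient."""
    n = probs.shape[0]
    p = probs.reshape(n, -1).astype(np.float64)
    t = truth.reshape(n, -1).astype(np.float64)
    inter = (p * t).sum(axis=1)
    sums = p.sum(axis=1) + t.sum(axis=1)
    num = 2.0 * inter + eps
    den = sums + eps
    loss = float(np.mean(1.0 - num / den))
    # d/dp_i of (1 - num/den) = -(2 t_i * den - num) / den^2, averaged over batch
    dp = -(2.0 * t * den[:, None] - num[:, None]) / (den ** 2)[:, None] / n
    return loss, dp.reshape(probs.shape).astype(np.float32)


def _hard_dice(pred_bin: np.ndarray, truth: np.ndarray) -> float:
    """Dice on binarized masks; empty-vs-empty counts as 1."""
    inter = float(np.logical_and(pred_bin, truth).sum())
    tot = float(pred_bin.sum() + truth.sum())
    if tot == 0:
        return 1.0
    return 2.0 * inter / tot


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: list[np.ndarray], cfg: TrainConfig) -> None:
        self.params = params
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.b1, self.b2, self.eps = cfg.adam_beta1, cfg.adam_beta2, cfg.adam_eps
        self.t = 0

    def step(self, grads: list[np.ndarray], lr: float) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _validation_dsc(model: UNet, pairs: list[LabeledPair],
                    batch_size: int) -> float:
    """Slice-wise mean Dice on un-augmented pairs at a 0.5 threshold."""
    scores = []
    for i in range(0, len(pairs), batch_size):
        chunk = pairs[i:i + batch_size]
        x = np.stack([p.image for p in chunk])[:, None]
        probs = model.forward(x, training=False)
        for j, p in enumerate(chunk):
            scores.append(_hard_dice(probs[j, 0] >= 0.5, p.mask))
    return float(np.mean(scores))


def train(model: UNet, train_pairs: list[LabeledPair],
          val_pairs: list[LabeledPair], cfg: TrainConfig,
          aug_params: AugmentationParams | None = None,
          ) -> tuple[UNet, TrainHistory]:
    """Train with fresh per-epoch augmentation and early stopping.

    Validation Dice is computed each epoch on un-augmented pairs with a
    0.5 probability threshold; the returned model carries the best-epoch
    weights.  Fully seeded via ``cfg.seed`` (and ``aug_params.seed``).
    """
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation sets must be non-empty")
    if aug_params is None:
        aug_params = AugmentationParams()

    steps_per_epoch = max(1, int(np.ceil(len(train_pairs) / cfg.batch_size)))
    schedule = cfg.lr_schedule or LRSchedule(
        warmup_steps=cfg.warmup_epochs * steps_per_epoch,
        peak_lr=cfg.peak_lr,
        decay_rate=cfg.decay_rate_per_epoch,
        decay_steps=steps_per_epoch,
    )

    rng = np.random.default_rng(cfg.seed)
    aug_rng = np.random.default_rng(aug_params.seed)
    opt = _Adam(model.parameters(), cfg)
    hist = TrainHistory()
    best_params: list[np.ndarray] | None = None
    best = -np.inf
    wait = 0
    step = 0

    for epoch in range(1, cfg.max_epochs + 1):
        augmented = [augment_pair(p, aug_params, aug_rng) for p in train_pairs]
        order = rng.permutation(len(augmented))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            chunk = [augmented[k] for k in order[i:i + cfg.batch_size]]
            x = np.stack([p.image for p in chunk])[:, None].astype(np.float32)
            t = np.stack([p.mask for p in chunk])[:, None].astype(np.float32)
            probs = model.forward(x, training=True)
            loss, dprobs = _soft_dice_batch(probs, t)
            grads = model.backward(dprobs)
            opt.step(grads, lr_at_step(step, schedule))
            losses.append(loss)
            step += 1

        val = _validation_dsc(model, val_pairs, cfg.batch_size)
        hist.train_loss.append(float(np.mean(losses)))
        hist.val_dsc.append(val)
        hist.lr.append(lr_at_step(step - 1, schedule))
        hist.stopped_epoch = epoch

        if val > best + cfg.min_delta:
            best = val
            hist.best_epoch = epoch
            best_params = [p.copy() for p in model.parameters()]
            wait = 0
        else:
            wait += 1
            if wait >= cfg.patience:
                break

    hist.best_val_dsc = float(best) if best > -np.inf else 0.0
    if best_params is not None:
        model.set_parameters(best_params)
    return model, hist


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict(model: UNet, images: np.ndarray, batch_size: int = 10) -> np.ndarray:
    """Probabilities for a batch of (N, H, W) images in [0, 1]."""
    images = np.asarray(images)
    outs = []
    for i in range(0, len(images), batch_size):
        x = images[i:i + batch_size][:, None]
        outs.append(model.forward(x, training=False)[:, 0])
    return np.concatenate(outs, axis=0)


def predict_stack(model: UNet, stack: SliceStack,
                  batch_size: int = 10) -> list[np.ndarray]:
    """Per-slice kidney probability maps on the native grid.

    Each slice is resampled to the model grid, inferred, and the
    probabilities mapped back bilinearly to ``(n_rows, n_cols)``.
    """
    size = model.cfg.input_size
    prepped = np.stack([prepare_for_model(s, size) for s in stack.slices])
    probs = predict(model, prepped, batch_size)
    return [resample_probabilities(p, stack.geometry) for p in probs]


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: UNet, path: str | Path,
                    train_cfg: TrainConfig | None = None) -> None:
    """Write weights (.npz) plus a JSON sidecar with the configurations."""
    path = Path(path)
    np.savez(path, **{f"p{i}": p for i, p in enumerate(model.parameters())})
    sidecar = {"unet": vars(model.cfg) | {},
               "train": (vars(train_cfg) | {}) if train_cfg else None}
    sidecar["unet"] = dict(sidecar["unet"])
    if sidecar["train"] is not None:
        sidecar["train"] = {k: (dict(vars(v)) if isinstance(v, LRSchedule) else v)
                            for k, v in sidecar["train"].items()}
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_checkpoint(path: str | Path) -> UNet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with open(path.with_suffix(".json")) as fh:
        sidecar = json.load(fh)
    model = build_unet(UNetConfig(**sidecar["unet"]))
    data = np.load(path)
    model.set_parameters([data[f"p{i}"] for i in range(len(data.files))])
    return model
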
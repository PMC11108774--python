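"""Momentum-contrast (MoCo) self-supervised feature extractor.

A query encoder is trained against a slowly updated key encoder and a FIFO
queue of negative keys with the InfoNCE loss

    L = -log[ exp(q.k+ / tau) / (exp(q.k+ / tau) + sum_{k-} exp(q.k- / tau)) ]

Two augmented views of each patch supply the positive pair; the queue holds
unit-norm keys from previous batches as negatives.  Only the query encoder
receives gradients; the key encoder follows by the momentum rule
theta_k <- m*theta_k + (1-m)*theta_q.  After pretraining the residual
backbone (pre-projection output) converts 224x224 patches into d-dimensional
feature vectors, which downstream MIL heads consume as bags.

Reference-scale hyperparameters: temperature 0.07, queue size 65,536,
momentum 0.999, SGD with initial lr 0.015 under cosine decay, weight decay
1e-4, batch 128, 200 epochs.  Every one of them scales down through
:class:`EncoderConfig` / :class:`MoCoTrainConfig` so the whole path runs on
one CPU at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.transform import resize as sk_resize

from ._autodiff import Adam, SGD, Tensor, concat, log_softmax  # noqa: F401  (SGD used)
from .bagio import PatchBag
from .errors import (
    DataError,
    DimensionError,
    EmptyBagError,
    ParameterError,
    ScheduleExhaustedError,
)
from .nn import ChannelNorm2d, Conv2d, Linear, Module

DEFAULT_TEMPERATURE = 0.07
DEFAULT_QUEUE_SIZE = 65_536
DEFAULT_MOMENTUM = 0.999
DEFAULT_INITIAL_LR = 0.015


# --------------------------------------------------------------- lr schedule
@dataclass
class LRSchedule:
    initial_lr: float = DEFAULT_INITIAL_LR
    total_epochs: int = 200
    epoch: int = 0


def cosine_lr(schedule: LRSchedule) -> float:
    """Cosine-decayed learning rate: lr0 * 0.5 * (1 + cos(pi * i / n))."""
    i, n = schedule.epoch, schedule.total_epochs
    if n < 1:
        raise ParameterError("total_epochs must be >= 1")
    if i < 0 or i > n:
        raise ScheduleExhaustedError(f"epoch {i} outside schedule of {n} epochs")
    return schedule.initial_lr * 0.5 * (1.0 + np.cos(np.pi * i / n))


# ------------------------------------------------------------------- updates
def momentum_update(theta_k, theta_q, m: float):
    """Elementwise exponential-moving-average update theta_k' = m*theta_k + (1-m)*theta_q."""
    if not (0.0 <= m <= 1.0):
        raise ParameterError("momentum coefficient must be in [0, 1]")
    if isinstance(theta_k, dict):
        if set(theta_k) != set(theta_q):
            raise DimensionError("parameter sets are incongruent (different keys)")
        out = {}
        for key in theta_k:
            a, b = np.asarray(theta_k[key]), np.asarray(theta_q[key])
            if a.shape != b.shape:
                raise DimensionError(f"shape mismatch for {key!r}: {a.shape} vs {b.shape}")
            out[key] = m * a + (1.0 - m) * b
        return out
    a, b = np.asarray(theta_k, dtype=float), np.asarray(theta_q, dtype=float)
    if a.shape != b.shape:
        raise DimensionError(f"shape mismatch: {a.shape} vs {b.shape}")
    return m * a + (1.0 - m) * b


def queue_update(queue: np.ndarray, new_keys: np.ndarray, capacity: int) -> np.ndarray:
    """FIFO key queue: append new keys, evict oldest so length <= capacity."""
    new_keys = np.atleast_2d(np.asarray(new_keys, dtype=float))
    if len(queue) and new_keys.shape[1] != queue.shape[1]:
        raise DimensionError("key dimension does not match queue entries")
    if len(new_keys) > capacity:
        raise ParameterError(f"batch of {len(new_keys)} keys exceeds queue capacity {capacity}")
    merged = np.concatenate([np.atleast_2d(queue), new_keys], axis=0) if len(queue) else new_keys
    return merged[-capacity:]


def info_nce_loss(q: np.ndarray, k_pos: np.ndarray, queue: np.ndarray,
                  temperature: float = DEFAULT_TEMPERATURE) -> float:
    """InfoNCE contrastive loss for one query against its positive key and the queue."""
    if temperature <= 0:
        raise ParameterError("temperature must be positive")
    q, k_pos = np.asarray(q, float), np.asarray(k_pos, float)
    if q.shape != k_pos.shape:
        raise DimensionError(f"q/k+ dimension mismatch: {q.shape} vs {k_pos.shape}")
    queue = np.atleast_2d(np.asarray(queue, float)) if np.size(queue) else np.empty((0, q.size))
    if queue.shape[0] and queue.shape[1] != q.size:
        raise DimensionError("queue entry dimension does not match q")
    logits = np.concatenate([[q @ k_pos], queue @ q]) / temperature
    shift = logits.max()
    return float(np.log(np.exp(logits - shift).sum()) - (logits[0] - shift))


# ------------------------------------------------------------------- encoder
@dataclass
class EncoderConfig:
    """Residual backbone + two-layer projection head.

    The reference scale mirrors a 50-layer residual network producing
    ``d``-dimensional features (default 1,024); tests use :meth:`tiny`.
    """

    stem_channels: int = 64
    stage_channels: Tuple[int, ...] = (256, 512, 1024, 2048)
    blocks_per_stage: int = 3
    d: int = 1024
    proj_hidden: Optional[int] = None  # default: d
    proj_dim: int = 128
    crop_size: int = 224
    # spatial channel normalization inside residual blocks; off by default so
    # global average pooling retains each image's chromatic profile
    normalize_blocks: bool = False

    def __post_init__(self):
        if self.d < 2:
            raise ParameterError("feature dimension d must be >= 2")
        if self.proj_hidden is None:
            self.proj_hidden = self.d

    @classmethod
    def tiny(cls, d: int = 64, crop_size: int = 64) -> "EncoderConfig":
        return cls(stem_channels=8, stage_channels=(8, 16, 24, 32),
                   blocks_per_stage=1, d=d, proj_hidden=d, proj_dim=32,
                   crop_size=crop_size)


class _BasicBlock(Module):
    def __init__(self, c_in, c_out, stride, rng, normalize=False):
        self.conv1 = Conv2d(c_in, c_out, 3, rng, stride=stride, padding=1)
        self.norm1 = ChannelNorm2d(c_out) if normalize else None
        self.conv2 = Conv2d(c_out, c_out, 3, rng, stride=1, padding=1)
        self.norm2 = ChannelNorm2d(c_out) if normalize else None
        self.proj = (Conv2d(c_in, c_out, 1, rng, stride=stride, padding=0, bias=False)
                     if (c_in != c_out or stride != 1) else None)

    def forward(self, x):
        y = self.conv1(x)
        if self.norm1 is not None:
            y = self.norm1(y)
        y = self.conv2(y.relu())
        if self.norm2 is not None:
            y = self.norm2(y)
        skip = self.proj(x) if self.proj is not None else x
        return (y + skip).relu()


class ResidualEncoder(Module):
    """Four-stage residual CNN with global average pooling and a feature head.

    Input: (3, H, W) in [0, 1], channel-standardized.  Output: d-vector from
    the backbone; :meth:`project` adds the contrastive MLP head (pretraining
    only — exported features are pre-projection backbone output).
    """

    def __init__(self, config: EncoderConfig, rng: np.random.Generator):
        self.config = config
        self.stem = Conv2d(3, config.stem_channels, 7, rng, stride=2, padding=3)
        self.stem_norm = ChannelNorm2d(config.stem_channels) if config.normalize_blocks else None
        blocks = []
        c_in = config.stem_channels
        for s, c_out in enumerate(config.stage_channels):
            for b in range(config.blocks_per_stage):
                stride = 2 if (s > 0 and b == 0) else 1
                blocks.append(_BasicBlock(c_in, c_out, stride, rng, config.normalize_blocks))
                c_in = c_out
        self.blocks = blocks
        self.feature_head = Linear(c_in, config.d, rng)
        self.proj1 = Linear(config.d, config.proj_hidden, rng)
        self.proj2 = Linear(config.proj_hidden, config.proj_dim, rng)
        # channel normalization statistics, filled from the training corpus
        self.channel_mean = np.array([0.5, 0.5, 0.5])
        self.channel_std = np.array([0.25, 0.25, 0.25])

    def backbone(self, x: Tensor) -> Tensor:
        h = self.stem(x)
        if self.stem_norm is not None:
            h = self.stem_norm(h)
        h = h.relu().maxpool2d(2)
        for blk in self.blocks:
            h = blk(h)
        pooled = h.reshape(h.shape[0], -1).mean(axis=1)  # global average pool
        return self.feature_head(pooled.reshape(1, -1))[0]

    def project_raw(self, feat: Tensor) -> Tensor:
        return self.proj2(self.proj1(feat.reshape(1, -1)).relu())[0]

    def project(self, feat: Tensor, center: np.ndarray = None) -> Tensor:
        """Unit-norm contrastive projection, optionally centered first.

        Centering by a running mean of key projections removes the shared
        mean component that would otherwise make all representations nearly
        collinear at small scale (no batch normalization is used)."""
        z = self.project_raw(feat)
        if center is not None:
            z = z - Tensor(center)
        norm = (z * z).sum().sqrt() + 1e-12
        return z / norm

    def preprocess(self, patch: np.ndarray) -> np.ndarray:
        x = np.asarray(patch, dtype=np.float64)
        if x.ndim == 2:
            x = np.stack([x] * 3, axis=-1)
        x = x / 255.0
        x = (x - self.channel_mean) / self.channel_std
        return x.transpose(2, 0, 1)

    def set_requires_grad(self, flag: bool):
        for p in self.parameters():
            p.requires_grad = flag


# -------------------------------------------------------------- augmentation
@dataclass
class AugmentationPolicy:
    """Ordered recipe: resize-crop, color jitter, grayscale, blur, flip, normalize."""

    crop_size: int = 224
    scale_range: Tuple[float, float] = (0.4, 1.0)
    jitter: float = 0.4
    grayscale_p: float = 0.2
    blur_p: float = 0.5
    flip_p: float = 0.5


def augment(img: np.ndarray, policy: AugmentationPolicy, rng: np.random.Generator) -> np.ndarray:
    """One random augmented view, returned as (H, W, 3) uint8 of crop_size."""
    x = np.asarray(img, dtype=np.float64)
    if x.ndim == 2:
        x = np.stack([x] * 3, axis=-1)
    h, w = x.shape[:2]
    # random resize-crop
    area = rng.uniform(*policy.scale_range) * h * w
    aspect = rng.uniform(3 / 4, 4 / 3)
    ch = int(np.clip(np.sqrt(area / aspect), 8, h))
    cw = int(np.clip(np.sqrt(area * aspect), 8, w))
    top = rng.integers(0, h - ch + 1)
    left = rng.integers(0, w - cw + 1)
    crop = x[top:top + ch, left:left + cw]
    crop = sk_resize(crop, (policy.crop_size, policy.crop_size, 3), order=1,
                     preserve_range=True, anti_aliasing=False)
    # color jitter (brightness/contrast/saturation)
    j = policy.jitter
    crop = crop * rng.uniform(1 - j, 1 + j)
    mean = crop.mean()
    crop = (crop - mean) * rng.uniform(1 - j, 1 + j) + mean
    gray = crop @ np.array([0.299, 0.587, 0.114])
    sat = rng.uniform(1 - j, 1 + j)
    crop = gray[..., None] + (crop - gray[..., None]) * sat
    if rng.random() < policy.grayscale_p:
        crop = np.repeat(gray[..., None], 3, axis=-1)
    if rng.random() < policy.blur_p:
        crop = ndimage.gaussian_filter(crop, sigma=(rng.uniform(0.1, 2.0),) * 2 + (0,))
    if rng.random() < policy.flip_p:
        crop = crop[:, ::-1]
    return np.clip(crop, 0, 255).astype(np.uint8)


# ------------------------------------------------------------------ training
@dataclass
class MoCoTrainConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    epochs: int = 200
    batch_size: int = 128
    initial_lr: float = DEFAULT_INITIAL_LR
    weight_decay: float = 1e-4
    sgd_momentum: float = 0.9
    momentum: float = DEFAULT_MOMENTUM       # key-encoder momentum m
    temperature: float = DEFAULT_TEMPERATURE
    queue_size: int = DEFAULT_QUEUE_SIZE
    augmentation: Optional[AugmentationPolicy] = None  # default: policy at crop size


@dataclass
class MoCoState:
    """Query/key encoders, momentum, temperature and the FIFO negative queue."""

    encoder_q: ResidualEncoder
    encoder_k: ResidualEncoder
    m: float
    temperature: float
    queue: np.ndarray
    capacity: int


@dataclass
class TrainLog:
    epoch_loss: list = field(default_factory=list)       # running training loss
    epoch_eval_loss: list = field(default_factory=list)  # vs frozen pairs/queue
    epoch_lr: list = field(default_factory=list)
    selected_epoch: Optional[int] = None


def train_moco(tiles: np.ndarray, config: MoCoTrainConfig, seed: int = 0
               ) -> Tuple[ResidualEncoder, TrainLog]:
    """Pretrain a residual encoder with momentum contrast on raster tiles.

    ``tiles`` is (N, H, W[, 3]) uint8.  Deterministic for a fixed seed.
    Returns the trained query encoder (its backbone is the feature extractor)
    and a log of per-epoch mean loss and learning rate.
    """
    tiles = np.asarray(tiles)
    if len(tiles) < 2:
        raise DataError("MoCo pretraining needs at least 2 images")
    rng = np.random.default_rng(seed)
    enc_cfg = config.encoder
    encoder_q = ResidualEncoder(enc_cfg, rng)
    encoder_k = ResidualEncoder(enc_cfg, rng)
    encoder_k.load_state_dict(encoder_q.state_dict())
    encoder_k.set_requires_grad(False)  # key encoder never updated by gradients

    # channel stats from the training corpus
    flat = tiles.reshape(-1, tiles.shape[-1]) / 255.0 if tiles.ndim == 4 else None
    if flat is not None:
        encoder_q.channel_mean = flat.mean(axis=0)
        encoder_q.channel_std = flat.std(axis=0) + 1e-6
        encoder_k.channel_mean = encoder_q.channel_mean
        encoder_k.channel_std = encoder_q.channel_std

    # queue initialized with unit random vectors so the loss is defined from
    # step 1, then burned in with real key projections below
    queue = rng.normal(size=(config.queue_size, enc_cfg.proj_dim))
    queue /= np.linalg.norm(queue, axis=1, keepdims=True)
    z_center = np.zeros(enc_cfg.proj_dim)  # running mean of raw key projections

    policy = config.augmentation or AugmentationPolicy(crop_size=enc_cfg.crop_size)
    policy.crop_size = enc_cfg.crop_size
    opt = SGD(encoder_q.parameters(), lr=config.initial_lr,
              momentum=config.sgd_momentum, weight_decay=config.weight_decay)
    log = TrainLog()

    # queue burn-in: one gradient-free pass of the key encoder so epoch-1
    # negatives are real keys rather than the random initialization
    burn = rng.permutation(len(tiles))[:min(len(tiles), config.queue_size)]
    burn_raw = []
    for idx in burn:
        view = augment(tiles[idx], policy, rng)
        burn_raw.append(encoder_k.project_raw(encoder_k.backbone(
            Tensor(encoder_k.preprocess(view)))).data)
    z_center = np.mean(burn_raw, axis=0)
    keys = np.stack(burn_raw) - z_center
    keys /= np.linalg.norm(keys, axis=1, keepdims=True) + 1e-12
    queue = queue_update(queue, keys, config.queue_size)

    # frozen evaluation set: fixed augmented view pairs and a fixed negative
    # queue/center, so per-epoch evaluation loss measures progress against a
    # stationary reference (the training loss target is nonstationary by design)
    eval_rng = np.random.default_rng(rng.integers(2**31))
    eval_idx = eval_rng.permutation(len(tiles))[:min(64, len(tiles))]
    eval_views = [(augment(tiles[i], policy, eval_rng),
                   augment(tiles[i], policy, eval_rng)) for i in eval_idx]
    eval_queue, eval_center = queue.copy(), z_center.copy()

    def eval_loss():
        total = 0.0
        for vq, vk in eval_views:
            q = encoder_q.project(encoder_q.backbone(
                Tensor(encoder_q.preprocess(vq))), eval_center).data
            k_raw = encoder_k.project_raw(encoder_k.backbone(
                Tensor(encoder_k.preprocess(vk)))).data
            k = k_raw - eval_center
            k /= np.linalg.norm(k) + 1e-12
            total += info_nce_loss(q, k, eval_queue, config.temperature)
        return total / len(eval_views)

    for epoch in range(config.epochs):
        lr = cosine_lr(LRSchedule(config.initial_lr, config.epochs, epoch))
        opt.lr = lr
        order = rng.permutation(len(tiles))
        losses = []
        for start in range(0, len(tiles), config.batch_size):
            batch = order[start:start + config.batch_size]
            qs, ks, k_raws = [], [], []
            for idx in batch:
                vq = augment(tiles[idx], policy, rng)
                vk = augment(tiles[idx], policy, rng)
                q = encoder_q.project(encoder_q.backbone(
                    Tensor(encoder_q.preprocess(vq), requires_grad=False)), z_center)
                k_raw = encoder_k.project_raw(encoder_k.backbone(
                    Tensor(encoder_k.preprocess(vk)))).data
                k = k_raw - z_center
                k = k / (np.linalg.norm(k) + 1e-12)
                qs.append(q)
                ks.append(k)
                k_raws.append(k_raw)
            # InfoNCE over positives + shared queue negatives
            loss_terms = []
            for q, k_pos in zip(qs, ks):
                pos = (q * Tensor(k_pos)).sum().reshape(1)
                neg = (Tensor(queue) @ q).reshape(-1)
                logits = concat([pos, neg]) / config.temperature
                loss_terms.append(-log_softmax(logits)[0])
            loss = sum(loss_terms[1:], loss_terms[0]) / len(loss_terms)
            opt.zero_grad()
            loss.backward()
            opt.step()
            # momentum update of the key encoder, then enqueue the new keys
            encoder_k.load_state_dict(momentum_update(
                encoder_k.state_dict(), encoder_q.state_dict(), config.momentum))
            queue = queue_update(queue, np.stack(ks), config.queue_size)
            z_center = 0.9 * z_center + 0.1 * np.mean(k_raws, axis=0)
            losses.append(loss.item())
        log.epoch_loss.append(float(np.mean(losses)))
        log.epoch_eval_loss.append(eval_loss())
        log.epoch_lr.append(lr)
    return encoder_q, log


def save_encoder(encoder: ResidualEncoder, path) -> None:
    """Persist encoder config, weights and channel statistics to .npz."""
    import json
    from dataclasses import asdict

    meta = json.dumps(asdict(encoder.config))
    state = {f"param::{k}": v for k, v in encoder.state_dict().items()}
    np.savez(path, __meta__=np.array(meta), channel_mean=encoder.channel_mean,
             channel_std=encoder.channel_std, **state)


def load_encoder(path) -> ResidualEncoder:
    import json

    with np.load(path, allow_pickle=False) as archive:
        cfg = EncoderConfig(**json.loads(str(archive["__meta__"])))
        enc = ResidualEncoder(cfg, np.random.default_rng(0))
        enc.load_state_dict({k[len("param::"):]: archive[k] for k in archive.files
                             if k.startswith("param::")})
        enc.channel_mean = archive["channel_mean"]
        enc.channel_std = archive["channel_std"]
    return enc


# ---------------------------------------------------------------- extraction
def extract_features(encoder: ResidualEncoder, bag: PatchBag,
                     resize_to: Optional[int] = None) -> np.ndarray:
    """Backbone features for every patch of a raster bag, as an (n, d) matrix.

    Row order equals patch order; deterministic for a fixed encoder.  Patches
    may optionally be down-sampled to ``resize_to`` pixels before encoding
    (the encoder is fully convolutional, so any input size works).
    """
    if bag.n == 0:
        raise EmptyBagError("cannot extract features from an empty bag")
    if not bag.has_rasters:
        raise DataError("extract_features requires raster patches")
    feats = []
    for patch in bag.patches:
        p = np.asarray(patch)
        if resize_to is not None and p.shape[0] != resize_to:
            zoom = (resize_to / p.shape[0], resize_to / p.shape[1]) + ((1,) if p.ndim == 3 else ())
            p = ndimage.zoom(p.astype(float), zoom, order=1)
        x = Tensor(encoder.preprocess(p))
        feats.append(encoder.backbone(x).data.copy())
    return np.stack(feats)
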
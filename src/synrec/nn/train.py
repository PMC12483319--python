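"""Supervised training of segmentation UNets and tiled prediction.

Targets are derived from instance labels: a binary foreground mask, a
one-voxel boundary rim (between touching objects and between object and
background) and, for the compartment variant, a normalized
distance-to-boundary regression channel trained with the same Dice-style
loss as an auxiliary task (weighted 1:1 via channel averaging).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.segmentation import find_boundaries

from ..volumes import InstanceSegmentation, Volume
from .loss import dice_loss_and_grad
from .optim import AdamW, ReduceLROnPlateau
from .unet import UNet, UNetConfig

__all__ = [
    "TrainConfig",
    "TrainedModel",
    "targets_from_labels",
    "train_supervised",
    "predict_tiled",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    lr_decay_factor: float = 0.5
    lr_plateau_epochs: int = 5
    iterations: int = 100_000
    patch_shape: tuple[int, ...] = (256, 256)
    batch_size: int = 1
    seed: int = 0
    epoch_iterations: int = 100
    val_fraction: float = 0.1
    n_val_batches: int = 4
    # label-preserving augmentation of training patches (flips / rot90 on
    # image+target; mild blur and additive noise on the image only)
    augment: bool = True
    aug_blur_sigma_range: tuple[float, float] = (0.0, 1.0)
    aug_noise_scale_range: tuple[float, float] = (0.0, 0.05)

    def __post_init__(self) -> None:
        if self.iterations <= 0:
            raise ValueError("iterations must be > 0")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction in [0, 1)")


@dataclass
class TrainedModel:
    """A UNet with the voxel size its training data were resampled to."""

    model: UNet
    voxel_size: np.ndarray | None = None
    log: list = field(default_factory=list)

    @property
    def cfg(self) -> UNetConfig:
        return self.model.cfg


def _as_array(x):
    if isinstance(x, Volume):
        return np.asarray(x.data, dtype=np.float32)
    if isinstance(x, InstanceSegmentation):
        return np.asarray(x.labels)
    return np.asarray(x)


def standardize(data: np.ndarray) -> np.ndarray:
    data = np.asarray(data, dtype=np.float32)
    sd = float(data.std())
    return (data - float(data.mean())) / (sd if sd > 0 else 1.0)


def targets_from_labels(labels, out_channels=("foreground", "boundary")) -> np.ndarray:
    """Channels-first (C, *spatial) training targets from instance labels."""
    lab = _as_array(labels)
    channels = []
    fg = lab > 0
    rim = find_boundaries(lab, mode="thick") if lab.max() > 0 else np.zeros_like(fg)
    for name in out_channels:
        if name == "foreground":
            channels.append(fg.astype(np.float32))
        elif name == "boundary":
            channels.append(rim.astype(np.float32))
        elif name == "boundary_distance":
            dist = ndi.distance_transform_edt(~rim) if rim.any() else np.zeros(lab.shape)
            peak = dist.max()
            channels.append((dist / peak if peak > 0 else dist).astype(np.float32))
        else:
            raise ValueError(f"unknown output channel {name!r}")
    return np.stack(channels)


def _sample_patch(rng, raw, target, patch_shape):
    """Random patch; volumes smaller than the patch are reflect-padded."""
    pads = [(0, max(p - s, 0)) for s, p in zip(raw.shape, patch_shape)]
    if any(p[1] for p in pads):
        raw = np.pad(raw, pads, mode="reflect")
        target = np.pad(target, [(0, 0)] + pads, mode="reflect")
    origin = tuple(
        rng.integers(0, s - p + 1) for s, p in zip(raw.shape, patch_shape)
    )
    sl = tuple(slice(o, o + p) for o, p in zip(origin, patch_shape))
    return raw[sl], target[(slice(None),) + sl]


def _augment_pair(rng, x, y, cfg):
    """Flips/rot90 on both image and target; blur + noise on the image."""
    nd = x.ndim
    for ax in range(nd):
        if rng.random() < 0.5:
            x = np.flip(x, axis=ax)
            y = np.flip(y, axis=1 + ax)
    if x.shape[-1] == x.shape[-2] and rng.random() < 0.5:
        k = int(rng.integers(1, 4))
        x = np.rot90(x, k, axes=(nd - 2, nd - 1))
        y = np.rot90(y, k, axes=(nd - 1, nd))
    x = np.ascontiguousarray(x)
    sigma = rng.uniform(*cfg.aug_blur_sigma_range)
    if sigma > 0:
        x = ndi.gaussian_filter(x, sigma)
    scale = rng.uniform(*cfg.aug_noise_scale_range)
    if scale > 0:
        drange = float(x.max() - x.min()) or 1.0
        x = x + rng.normal(0.0, scale * drange, size=x.shape).astype(np.float32)
    return x, np.ascontiguousarray(y)


def _make_batch(rng, volumes, targets, patch_shape, batch_size, cfg=None):
    xs, ys = [], []
    for _ in range(batch_size):
        i = int(rng.integers(0, len(volumes)))
        x, y = _sample_patch(rng, volumes[i], targets[i], patch_shape)
        if cfg is not None and cfg.augment:
            x, y = _augment_pair(rng, x, y, cfg)
        xs.append(x[..., None])
        ys.append(np.moveaxis(y, 0, -1))
    return np.stack(xs), np.stack(ys)


def train_supervised(model: UNet, data, cfg: TrainConfig, voxel_size=None):
    """Train a UNet on (volume, instance labels) pairs.

    ``data`` is a sequence of pairs; the validation split is by volume
    (default 10%), never by patch, to avoid leakage. Returns a
    :class:`TrainedModel` holding the checkpoint with the lowest
    validation loss and a per-epoch log.
    """
    if len(data) == 0:
        raise ValueError("empty training set")
    volumes = [standardize(_as_array(v)) for v, _ in data]
    targets = [targets_from_labels(l, model.cfg.out_channels) for _, l in data]
    if voxel_size is None:
        vols = [v for v, _ in data if isinstance(v, Volume)]
        voxel_size = vols[0].voxel_size if vols else None

    n_val = max(1, round(cfg.val_fraction * len(data))) if len(data) > 1 else 0
    order = np.random.default_rng(cfg.seed).permutation(len(data))
    val_idx = order[:n_val] if n_val else order[:1]  # single volume: reused
    train_idx = order[n_val:] if n_val else order
    tr_vols = [volumes[i] for i in train_idx]
    tr_tgts = [targets[i] for i in train_idx]
    va_vols = [volumes[i] for i in val_idx]
    va_tgts = [targets[i] for i in val_idx]

    val_rng = np.random.default_rng(cfg.seed + 1)
    val_batches = [
        _make_batch(val_rng, va_vols, va_tgts, cfg.patch_shape, cfg.batch_size)
        for _ in range(cfg.n_val_batches)
    ]

    def val_loss():
        total = 0.0
        for x, y in val_batches:
            pred = model.forward(x)
            loss, _ = dice_loss_and_grad(pred, y)
            total += loss
        return total / len(val_batches)

    opt = AdamW(lr=cfg.learning_rate)
    sched = ReduceLROnPlateau(
        opt, factor=cfg.lr_decay_factor, patience=cfg.lr_plateau_epochs
    )
    rng = np.random.default_rng(cfg.seed + 2)
    log: list[dict] = []
    best = (np.inf, model.state_dict())
    train_acc, n_acc = 0.0, 0
    for it in range(1, cfg.iterations + 1):
        x, y = _make_batch(rng, tr_vols, tr_tgts, cfg.patch_shape, cfg.batch_size, cfg)
        pred = model.forward(x)
        loss, grad = dice_loss_and_grad(pred, y)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite training loss at iteration {it}")
        model.backward(grad)
        opt.step(model.parameters(), model.gradients())
        train_acc += loss
        n_acc += 1
        if it % cfg.epoch_iterations == 0 or it == cfg.iterations:
            vl = val_loss()
            reduced = sched.step(vl)
            entry = {
                "iteration": it,
                "train_loss": train_acc / max(n_acc, 1),
                "val_loss": vl,
                "lr": opt.lr,
                "lr_reduced": reduced,
            }
            log.append(entry)
            train_acc, n_acc = 0.0, 0
            if vl < best[0]:
                best = (vl, model.state_dict())
    model.load_state_dict(best[1])
    return TrainedModel(model, voxel_size=voxel_size, log=log)


def _pad_to(shape, divisor):
    return tuple(-(-s // d) * d * 1 for s, d in zip(shape, divisor))


def predict_tiled(model, volume, tile_shape=None, halo=None, normalize=True):
    """Seamless tiled prediction; returns channels-first maps (C, *spatial).

    The volume is reflect-padded so every tile (with its halo) is valid;
    only the tile centers are written to the output, so tiled and untiled
    prediction agree up to floating-point noise.
    """
    net = model.model if isinstance(model, TrainedModel) else model
    data = _as_array(volume)
    if normalize:
        data = standardize(data)
    div = np.asarray(net.cfg.divisor)
    nd = len(div)
    if data.ndim != nd:
        raise ValueError(f"model is {nd}D but volume is {data.ndim}D")
    shape = np.asarray(data.shape)
    if tile_shape is None:
        tile = np.asarray(_pad_to(data.shape, div))
    else:
        tile = np.asarray(tile_shape)
        if np.any(tile % div):
            raise ValueError(f"tile_shape must be divisible by {tuple(div)}")
        if np.any(tile < div):
            raise ValueError("tile smaller than the minimum valid input")
    if halo is None:
        halo = 4 * div  # covers the receptive field to float tolerance
    halo = np.broadcast_to(np.asarray(halo), (nd,))
    halo = (-(-halo // div)) * div  # round halo up to divisibility
    n_ch = len(net.cfg.out_channels)
    out = np.zeros((n_ch,) + data.shape, dtype=np.float32)
    # pad so that every tile+halo block lies inside
    padded_shape = np.asarray(_pad_to(data.shape, tile))
    pad = [(h, int(ps - s + h)) for s, ps, h in zip(data.shape, padded_shape, halo)]
    padded = np.pad(data, pad, mode="reflect")
    for origin in np.ndindex(*(padded_shape // tile)):
        start = np.asarray(origin) * tile
        block = padded[
            tuple(slice(s, s + t + 2 * h) for s, t, h in zip(start, tile, halo))
        ]
        pred = net.predict(block)
        center = pred[
            (slice(None),)
            + tuple(slice(h, h + t) for t, h in zip(tile, halo))
        ]
        stop = np.minimum(start + tile, shape)
        keep = tuple(slice(0, int(e - s)) for s, e in zip(start, stop))
        if all(k.stop > 0 for k in keep):
            out[(slice(None),) + tuple(slice(int(s), int(e)) for s, e in zip(start, stop))] = center[
                (slice(None),) + keep
            ]
    return out


def save_checkpoint(trained: TrainedModel, path) -> None:
    """Self-describing archive: weights + architecture + training voxel size."""
    net = trained.model if isinstance(trained, TrainedModel) else trained
    meta = {
        "config": {
            "dimensionality": net.cfg.dimensionality,
            "levels": net.cfg.levels,
            "initial_features": net.cfg.initial_features,
            "feature_growth": net.cfg.feature_growth,
            "anisotropic_first_downsample": net.cfg.anisotropic_first_downsample,
            "in_channels": net.cfg.in_channels,
            "out_channels": list(net.cfg.out_channels),
            "convs_per_block": net.cfg.convs_per_block,
        },
        "voxel_size": (
            None
            if getattr(trained, "voxel_size", None) is None
            else list(map(float, np.atleast_1d(trained.voxel_size)))
        ),
    }
    arrays = {f"param/{k}": v for k, v in net.parameters().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> TrainedModel:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        cfg_d = dict(meta["config"])
        cfg_d["out_channels"] = tuple(cfg_d["out_channels"])
        cfg = UNetConfig(**cfg_d)
        net = UNet(cfg)
        state = {
            k[len("param/") :]: archive[k] for k in archive.files if k.startswith("param/")
        }
    net.load_state_dict(state)
    vs = meta.get("voxel_size")
    return TrainedModel(net, voxel_size=None if vs is None else np.asarray(vs))
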
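"""Training harness: Adam with exponential learning-rate decay, he-normal
initialization (applied at build), paired image/mask augmentation and
early stopping on validation loss.

The learning rate follows ``lr = ilr * 0.9 ** (epoch / 10)`` with a
real-valued exponent by default; ``floor_schedule`` switches to the
integer-division reading (the two coincide at multiples of 10).
"""
from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .architecture import SegmentationModel
from .losses import LossConfig, PixelBatch, hybrid_loss, hybrid_loss_grad

__all__ = ["TrainConfig", "AugmentConfig", "Adam", "lr_schedule",
           "augment_pair", "fit", "History"]


@dataclass(frozen=True)
class AugmentConfig:
    """Affine augmentation ranges applied identically to image and mask."""

    shear: float = 0.5             # shear intensity (radians)
    rotation: float = 50.0         # degrees, drawn in [-r, r]
    zoom: float = 0.2              # scale drawn in [1-z, 1+z]
    horizontal_flip: bool = True
    width_shift: float = 0.2       # fraction of width
    height_shift: float = 0.2
    fill_mode: str = "reflect"


@dataclass
class TrainConfig:
    """Defaults mirror the polyp learning setting: dice+WCE loss, initial
    learning rate 3e-4, 200 epochs, batch 8, 224 px inputs, augmentation
    on, 80/20 train/validation split."""

    ilr: float = 3e-4
    epochs: int = 200
    batch_size: int = 8
    loss: LossConfig = field(default_factory=lambda: LossConfig("dice_wce"))
    input_size: int = 224
    augment: bool = True
    augment_config: AugmentConfig = field(default_factory=AugmentConfig)
    early_stopping_patience: int = 10
    validation_fraction: float = 0.2
    floor_schedule: bool = False
    deep_supervision: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, text):
        import yaml
        d = yaml.safe_load(text)
        if "loss" in d and isinstance(d["loss"], (str, dict)):
            d["loss"] = LossConfig(d["loss"]) if isinstance(d["loss"], str) \
                else LossConfig(**d["loss"])
        if "augment_config" in d and isinstance(d["augment_config"], dict):
            d["augment_config"] = AugmentConfig(**d["augment_config"])
        return cls(**d)


def lr_schedule(ilr: float, epoch: int, floor: bool = False) -> float:
    """ilr * 0.9 ** (epoch / 10)."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    e = epoch // 10 if floor else epoch / 10.0
    return ilr * 0.9 ** e


class Adam:
    def __init__(self, params, lr=3e-4, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad * p.grad
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _affine_params(cfg: AugmentConfig, rng):
    theta = np.deg2rad(rng.uniform(-cfg.rotation, cfg.rotation)) \
        if cfg.rotation else 0.0
    shear = rng.uniform(-cfg.shear, cfg.shear) if cfg.shear else 0.0
    zoom = rng.uniform(1.0 - cfg.zoom, 1.0 + cfg.zoom) if cfg.zoom else 1.0
    flip = bool(cfg.horizontal_flip and rng.random() < 0.5)
    return theta, shear, zoom, flip, \
        rng.uniform(-cfg.height_shift, cfg.height_shift) if cfg.height_shift else 0.0, \
        rng.uniform(-cfg.width_shift, cfg.width_shift) if cfg.width_shift else 0.0


def augment_pair(image, mask, aug_config: AugmentConfig, rng):
    """One random affine transform (shear, rotation, zoom, flip, shift)
    applied identically to image and mask; reflection fill; the mask is
    warped nearest-neighbour and re-binarized."""
    image = np.asarray(image, dtype=np.float32)
    mask = np.asarray(mask)
    sp = image.shape[-2:]
    if mask.shape[-2:] != sp:
        raise ValueError("image and mask must be spatially congruent")
    theta, shear, zoom, flip, dy, dx = _affine_params(aug_config, rng)

    ct, st = np.cos(theta), np.sin(theta)
    rot = np.array([[ct, -st], [st, ct]])
    shr = np.array([[1.0, -np.sin(shear)], [0.0, np.cos(shear)]])
    mat = (rot @ shr) * zoom
    if flip:
        mat = mat @ np.array([[1.0, 0.0], [0.0, -1.0]])
    inv = np.linalg.inv(mat)
    center = (np.array(sp) - 1) / 2.0
    offset = center - inv @ center + inv @ np.array([dy * sp[0], dx * sp[1]])

    def warp(channel, order):
        return ndimage.affine_transform(channel, inv, offset=offset,
                                        order=order,
                                        mode=aug_config.fill_mode)

    if image.ndim == 2:
        img_out = warp(image, 1)
    else:
        img_out = np.stack([warp(c, 1) for c in image])
    msk = mask.astype(np.float32)
    if msk.ndim == 2:
        msk_out = warp(msk, 0)
    else:
        msk_out = np.stack([warp(c, 0) for c in msk])
    return img_out.astype(np.float32), (msk_out > 0.5).astype(mask.dtype)


@dataclass
class History:
    epochs: list = field(default_factory=list)

    def append(self, **row):
        self.epochs.append(row)

    def to_jsonl(self, path):
        with open(path, "w") as fh:
            for row in self.epochs:
                fh.write(json.dumps(row) + "\n")

    def __getitem__(self, key):
        return [e[key] for e in self.epochs]


def _loss_and_grad(model, x, y, config: TrainConfig, rng):
    outputs = model.forward(x, training=True, rng=rng)
    names = ["final_output"]
    if config.deep_supervision:
        names += [n for n in outputs if n.startswith("sub_output")]
    total = 0.0
    for name in names:
        out = outputs[name]
        k = out.data[:, 0]
        total += hybrid_loss(PixelBatch(y, k), config.loss)
        out.backward(hybrid_loss_grad(y, k, config.loss)[:, None])
    return total / len(names)


def _dsc_of(model, x, y):
    pred = model.predict(x)["final_output"][:, 0] >= 0.5
    truth = np.asarray(y) > 0.5
    tp = float(np.sum(pred & truth))
    denom = pred.sum() + truth.sum()
    return 1.0 if denom == 0 else 2.0 * tp / denom


def fit(model: SegmentationModel, images, masks, config: TrainConfig,
        val_images=None, val_masks=None, history_path=None, verbose=False):
    """Train; returns (history, best_state_dict).

    If no validation set is given, ``validation_fraction`` of the data is
    split off (the split and all shuffling/augmentation derive from
    ``config.seed``).  Early stopping monitors validation loss with the
    configured patience; the best-validation weights are returned.  When
    the data is too small to split (or validation_fraction is 0) the
    training loss is monitored instead.
    """
    images = np.asarray(images, dtype=np.float32)
    masks = np.asarray(masks)
    if len(images) == 0:
        raise ValueError("empty dataset")
    if images.shape[0] != masks.shape[0]:
        raise ValueError("images and masks disagree in length")
    rng = np.random.default_rng(config.seed)

    if val_images is None and config.validation_fraction > 0 \
            and len(images) >= 5:
        n_val = max(1, int(round(config.validation_fraction * len(images))))
        perm = rng.permutation(len(images))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        val_images, val_masks = images[val_idx], masks[val_idx]
        images, masks = images[tr_idx], masks[tr_idx]

    opt = Adam([p for p in model.parameters()], lr=config.ilr)
    history = History()
    best_loss, best_state, best_epoch = np.inf, None, -1

    for epoch in range(config.epochs):
        opt.lr = lr_schedule(config.ilr, epoch, config.floor_schedule)
        perm = rng.permutation(len(images))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(images), config.batch_size):
            idx = perm[start:start + config.batch_size]
            xb = images[idx]
            yb = masks[idx].astype(np.float32)
            if config.augment:
                pairs = [augment_pair(x_, y_, config.augment_config, rng)
                         for x_, y_ in zip(xb, yb)]
                xb = np.stack([p[0] for p in pairs])
                yb = np.stack([p[1] for p in pairs]).astype(np.float32)
            opt.zero_grad()
            epoch_loss += _loss_and_grad(model, xb, yb, config, rng)
            n_batches += 1
            opt.step()
        train_loss = epoch_loss / n_batches
        train_dsc = _dsc_of(model, images, masks)
        row = dict(epoch=epoch, lr=opt.lr, train_loss=train_loss,
                   train_dsc=train_dsc)
        if val_images is not None:
            vout = model.predict(val_images)["final_output"][:, 0]
            row["val_loss"] = hybrid_loss(
                PixelBatch(val_masks.astype(np.float32), vout), config.loss)
            row["val_dsc"] = _dsc_of(model, val_images, val_masks)
            monitor = row["val_loss"]
        else:
            monitor = train_loss
        history.append(**row)
        if verbose:
            print(" ".join(f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
                           for k, v in row.items()))
        if monitor < best_loss:
            best_loss, best_epoch = monitor, epoch
            best_state = copy.deepcopy(model.state_dict())
        elif epoch - best_epoch >= config.early_stopping_patience:
            break
    if history_path:
        history.to_jsonl(history_path)
    return history, best_state
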
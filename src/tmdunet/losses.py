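"""Hybrid segmentation losses: dice + (weighted) binary cross-entropy.

The training objective is ``L = L_dice + L_ce`` where the cross-entropy
term is plain BCE for balanced data and class-weighted (WCE) otherwise.
As printed in the source formulation, the WCE weight ``w`` — described as
the foreground-class weight — multiplies the *background* error term and
``1 - w`` the foreground term; this module follows the printed formula
literally (see docs/methods.md for the discussion).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LossConfig", "PixelBatch", "dice_loss", "bce_loss", "wce_loss",
           "hybrid_loss", "hybrid_loss_grad", "EPS"]

EPS = 1e-7           # probability clipping before logarithms
KINDS = ("dice_bce", "dice_wce")
_TABLE_NAMES = {"DC+BCE": "dice_bce", "DC+WCE": "dice_wce"}


@dataclass(frozen=True)
class LossConfig:
    kind: str = "dice_bce"
    foreground_weight: float = 0.5
    smooth: float = 1.0

    def __post_init__(self):
        kind = _TABLE_NAMES.get(self.kind, self.kind)
        object.__setattr__(self, "kind", kind)
        if kind not in KINDS:
            raise ValueError(f"unknown loss kind {self.kind!r}")
        if not (0.0 < self.foreground_weight < 1.0):
            raise ValueError("foreground_weight must lie in (0, 1)")
        if self.smooth < 0.0:
            raise ValueError("smooth must be nonnegative")


@dataclass
class PixelBatch:
    """Ground-truth labels y in {0,1} and predictions k in [0,1]."""

    y: np.ndarray
    k: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.float64)
        self.k = np.asarray(self.k, dtype=np.float64)
        if self.y.shape != self.k.shape:
            raise ValueError("y and k must have congruent shapes")
        if self.y.size < 1:
            raise ValueError("batch must contain at least one pixel")

    @property
    def n(self):
        return self.y.size


def _clip(k):
    return np.clip(k, EPS, 1.0 - EPS)


def dice_loss(batch: PixelBatch, smooth: float = 1.0) -> float:
    """1 - (2*sum(y*k) + smooth) / (sum(y + k) + smooth)."""
    num = 2.0 * float(np.sum(batch.y * batch.k)) + smooth
    den = float(np.sum(batch.y + batch.k)) + smooth
    if den == 0.0:
        raise ZeroDivisionError("dice loss undefined: empty masks and smooth=0")
    return 1.0 - num / den

def bce_loss(batch: PixelBatch) -> float:
    k = _clip(batch.k)
    return float(-np.mean(batch.y * np.log(k) + (1.0 - batch.y) * np.log1p(-k)))

def wce_loss(batch: PixelBatch, w: float) -> float:
    if not (0.0 < w < 1.0):
        raise ValueError("foreground weight must lie in (0, 1)")
    k = _clip(batch.k)
    return float(-np.mean((1.0 - w) * batch.y * np.log(k)
                          + w * (1.0 - batch.y) * np.log1p(-k)))


def hybrid_loss(batch: PixelBatch, config: LossConfig) -> float:
    ce = bce_loss(batch) if config.kind == "dice_bce" \
        else wce_loss(batch, config.foreground_weight)
    return dice_loss(batch, config.smooth) + ce


def hybrid_loss_grad(y, k, config: LossConfig):
    """Analytic d(hybrid loss)/dk, the seed for network backpropagation."""
    y = np.asarray(y, dtype=np.float64)
    kc = _clip(np.asarray(k, dtype=np.float64))
    a = 2.0 * np.sum(y * kc) + config.smooth
    b = np.sum(y + kc) + config.smooth
    ddice = (a - 2.0 * y * b) / (b * b)
    wf, wb = (1.0, 1.0) if config.kind == "dice_bce" else \
        (1.0 - config.foreground_weight, config.foreground_weight)
    dce = -(wf * y / kc - wb * (1.0 - y) / (1.0 - kc)) / y.size
    return (ddice + dce).astype(np.float32)


def class_balance_weight(masks) -> float:
    """Default WCE weight: the training-set foreground-pixel fraction, so
    the printed formula up-weights the rarer class's error term."""
    masks = np.asarray(masks)
    frac = float(masks.mean())
    return min(max(frac, 1e-3), 1.0 - 1e-3)
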
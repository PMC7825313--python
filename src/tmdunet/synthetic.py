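"""Deterministic synthetic images, masks and volumes.

Blob images stand in for the segmentation datasets: each image is a union
of random ellipses at high intensity over a darker background, with
additive Gaussian noise; the mask is the exact ellipse union.  Volumes
emulate organ CT stacks: an organ span of slices containing a blob,
surrounded by foreground-free slices, for exercising the slice operators.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import SliceVolume

__all__ = ["SynthSpec", "generate_blobs", "generate_volume"]

_FG_INTENSITY = 0.8
_BG_INTENSITY = 0.2
_MAX_TRIES = 200


@dataclass(frozen=True)
class SynthSpec:
    n_images: int = 8
    size: int = 128
    channels: int = 1
    n_blobs: tuple = (1, 3)
    foreground_fraction: tuple = (0.05, 0.35)
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.channels not in (1, 3):
            raise ValueError("channels must be 1 or 3")
        lo, hi = self.foreground_fraction
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError("foreground_fraction must be an increasing "
                             "sub-range of [0, 1]")
        if self.size % 16 != 0:
            raise ValueError("size must be divisible by 16 (network input)")


def _ellipse_mask(size, cy, cx, ry, rx, theta, out):
    yy, xx = np.mgrid[0:size, 0:size]
    y, x = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (x * ct + y * st) / rx
    v = (-x * st + y * ct) / ry
    out |= (u * u + v * v) <= 1.0


def _one_mask(spec: SynthSpec, rng):
    lo, hi = spec.foreground_fraction
    for _ in range(_MAX_TRIES):
        mask = np.zeros((spec.size, spec.size), dtype=bool)
        n = int(rng.integers(spec.n_blobs[0], spec.n_blobs[1] + 1))
        for _ in range(n):
            cy, cx = rng.uniform(0.15, 0.85, 2) * spec.size
            ry, rx = rng.uniform(0.05, 0.30, 2) * spec.size
            _ellipse_mask(spec.size, cy, cx, ry, rx,
                          rng.uniform(0, np.pi), mask)
            if mask.mean() >= lo:
                break
        if lo <= mask.mean() <= hi:
            return mask
    raise ValueError(
        f"could not realize foreground fraction in {spec.foreground_fraction} "
        f"for size {spec.size} and n_blobs {spec.n_blobs}")


def generate_blobs(spec: SynthSpec):
    """Images (n, C, H, W) float32 in [0,1] and masks (n, H, W) uint8,
    bit-identical for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    images = np.empty((spec.n_images, spec.channels, spec.size, spec.size),
                      dtype=np.float32)
    masks = np.empty((spec.n_images, spec.size, spec.size), dtype=np.uint8)
    for j in range(spec.n_images):
        m = _one_mask(spec, rng)
        img = np.where(m, _FG_INTENSITY, _BG_INTENSITY)
        img = img[None].repeat(spec.channels, axis=0)
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        images[j] = np.clip(img, 0.0, 1.0)
        masks[j] = m
    return images, masks


def generate_volume(n_slices: int, size: int, organ_span, seed: int = 0):
    """A SliceVolume whose slices inside ``organ_span`` (half-open 0-based
    range) contain one elliptical blob; all other slices are empty."""
    lo, hi = organ_span
    if not (0 <= lo <= hi <= n_slices):
        raise ValueError(f"organ span {organ_span} outside [0, {n_slices}]")
    rng = np.random.default_rng(seed)
    slices = rng.normal(_BG_INTENSITY, 0.02,
                        (n_slices, size, size)).astype(np.float32)
    masks = np.zeros((n_slices, size, size), dtype=np.uint8)
    for i in range(lo, hi):
        m = np.zeros((size, size), dtype=bool)
        cy, cx = rng.uniform(0.3, 0.7, 2) * size
        ry, rx = rng.uniform(0.1, 0.25, 2) * size
        _ellipse_mask(size, cy, cx, ry, rx, rng.uniform(0, np.pi), m)
        masks[i] = m
        slices[i][m] = _FG_INTENSITY
    return SliceVolume(slices=np.clip(slices, 0.0, 1.0), masks=masks)
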
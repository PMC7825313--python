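"""Dataset-preparation operators.

These mirror the study preprocessing recipes: sliding-window tiling of
large micrographs, Hounsfield-unit (or plain intensity) windowing of
CT/MRI volumes, center cropping, bilinear/nearest resizing, stacking of
adjacent slices into a 3-channel image, and decimation of foreground-free
slices (keep one of every three consecutive empty slices).

Coordinates are 0-based; windows are half-open ``[origin, origin+window)``.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = ["TileGrid", "WindowSpec", "SliceVolume", "tile", "assemble_tiles",
           "intensity_window", "center_crop", "stack_adjacent",
           "decimate_empty", "resize", "write_tile_manifest"]


@dataclass(frozen=True)
class TileGrid:
    """Deterministic sliding-window decomposition bookkeeping."""

    image_shape: tuple
    window: int
    stride: int
    origins: tuple = field(init=False)

    def __post_init__(self):
        h, w = self.image_shape[:2]
        for size, axis in ((h, "rows"), (w, "cols")):
            if (size - self.window) % self.stride != 0 or size < self.window:
                raise ValueError(
                    f"geometry not tileable along {axis}: size {size}, "
                    f"window {self.window}, stride {self.stride}")
        rows = (h - self.window) // self.stride + 1
        cols = (w - self.window) // self.stride + 1
        object.__setattr__(self, "origins", tuple(
            (r * self.stride, c * self.stride)
            for r in range(rows) for c in range(cols)))

    @property
    def tiles_per_axis(self):
        h, w = self.image_shape[:2]
        return ((h - self.window) // self.stride + 1,
                (w - self.window) // self.stride + 1)

    @property
    def n_tiles(self):
        return len(self.origins)


def tile(image, window: int, stride: int):
    """Extract row-major sliding-window tiles; rejects non-divisible
    geometries rather than padding partial windows."""
    image = np.asarray(image)
    grid = TileGrid(image.shape, window, stride)
    tiles = [image[r:r + window, c:c + window] for r, c in grid.origins]
    return tiles, grid


def assemble_tiles(tiles, grid: TileGrid):
    """Average-overlap reconstruction of the tiled image."""
    out = np.zeros(grid.image_shape, dtype=np.float64)
    cov = np.zeros(grid.image_shape[:2], dtype=np.float64)
    for t, (r, c) in zip(tiles, grid.origins):
        out[r:r + grid.window, c:c + grid.window] += t
        cov[r:r + grid.window, c:c + grid.window] += 1.0
    if (cov == 0).any():
        raise ValueError("grid does not cover the image")
    return out / (cov if out.ndim == 2 else cov[..., None])


@dataclass(frozen=True)
class WindowSpec:
    """Intensity window, e.g. Hounsfield units [-200, 250] for abdominal CT."""

    low: float
    high: float

    def __post_init__(self):
        if self.low >= self.high:
            raise ValueError("window low must be below high")


def intensity_window(volume, spec: WindowSpec):
    """Clip to [low, high] and map affinely to [0, 1]."""
    v = np.asarray(volume, dtype=np.float64)
    return (np.clip(v, spec.low, spec.high) - spec.low) / (spec.high - spec.low)


def center_crop(image, size: int):
    """Centered square crop; an odd margin leaves the extra pixel on the
    trailing side."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    if size > h or size > w:
        raise ValueError(f"crop size {size} exceeds image {h}x{w}")
    top, left = (h - size) // 2, (w - size) // 2
    return image[top:top + size, left:left + size]


@dataclass
class SliceVolume:
    """An ordered stack of 2-D slices with per-slice foreground flags."""

    slices: np.ndarray                 # (n, H, W)
    masks: np.ndarray = None           # (n, H, W) binary or None
    flags: np.ndarray = field(init=False)

    def __post_init__(self):
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3:
            raise ValueError("expect a (n_slices, H, W) stack")
        if self.masks is not None:
            self.masks = np.asarray(self.masks)
            if self.masks.shape != self.slices.shape:
                raise ValueError("masks must be congruent with slices")
            self.flags = self.masks.reshape(len(self.masks), -1).any(axis=1)
        else:
            self.flags = np.zeros(len(self.slices), dtype=bool)

    def __len__(self):
        return len(self.slices)


def stack_adjacent(volume: SliceVolume, index: int):
    """3-channel image (previous, current, next slice); the first and last
    slice duplicate themselves at the missing neighbour."""
    n = len(volume)
    if n == 0:
        raise ValueError("empty volume")
    if not (0 <= index < n):
        raise IndexError(f"slice index {index} out of range 0..{n - 1}")
    prev_i = max(index - 1, 0)
    next_i = min(index + 1, n - 1)
    return np.stack([volume.slices[prev_i], volume.slices[index],
                     volume.slices[next_i]], axis=0)


def decimate_empty(volume: SliceVolume):
    """Keep all foreground slices; inside each run of consecutive
    foreground-free slices keep every third slice starting from the first
    (two of three empty slices are excluded).  Returns kept indices."""
    kept = []
    run = 0
    for i, fg in enumerate(volume.flags):
        if fg:
            run = 0
            kept.append(i)
        else:
            if run % 3 == 0:
                kept.append(i)
            run += 1
    return kept


def resize(image, size, is_mask=False):
    """Resize to size x size: bilinear for intensities, nearest-neighbour
    for masks (so binary masks stay binary)."""
    image = np.asarray(image)
    shape = (size, size) + image.shape[2:]
    if is_mask:
        out = _sk_resize(image, shape, order=0, anti_aliasing=False,
                         preserve_range=True)
        return out.astype(image.dtype)
    return _sk_resize(image, shape, order=1, anti_aliasing=False,
                      preserve_range=True)


def write_tile_manifest(path, image_id, grid: TileGrid):
    """CSV manifest: image_id, row, col, origin_y, origin_x."""
    rows, cols = grid.tiles_per_axis
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["image_id", "row", "col", "origin_y", "origin_x"])
        for idx, (oy, ox) in enumerate(grid.origins):
            w.writerow([image_id, idx // cols, idx % cols, oy, ox])
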
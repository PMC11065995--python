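"""Training-time augmentation: flips, shift, rotation, window contrast, grid distortion.

Every geometric transform is sampled once per call and applied identically
to the image and its mask (bilinear for intensities, nearest-neighbour for
labels, zero-fill outside the field of view — background is dark on
FLAIR); the contrast transform changes the display window width about
mid-gray and touches the image only. Augmentation is applied to all
slices, with or without lesions, and only at training time.

The source gives no magnitudes, so the defaults are conventional
medical-imaging ranges: each transform fires with probability 0.5, shift
up to 10% of the image size, rotation up to 15 degrees, window gain in
[0.7, 1.3], and a 5x5-cell grid distortion with up to 10% cell
displacement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize as _sk_resize

__all__ = ["AugmentConfig", "apply_augmentations", "window_contrast", "grid_distortion"]


@dataclass
class AugmentConfig:
    hflip_p: float = 0.5
    vflip_p: float = 0.5
    shift_p: float = 0.5
    shift_frac_max: float = 0.10
    rotate_p: float = 0.5
    rotate_deg_max: float = 15.0
    window_p: float = 0.5
    window_gain_range: tuple = (0.7, 1.3)
    grid_p: float = 0.5
    grid_distort_strength: float = 0.10
    grid_cells: int = 5

    def __post_init__(self):
        for p in (self.hflip_p, self.vflip_p, self.shift_p, self.rotate_p, self.window_p, self.grid_p):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")
        if self.shift_frac_max < 0 or self.rotate_deg_max < 0 or self.grid_distort_strength < 0:
            raise ValueError("ranges must be non-negative")
        if min(self.window_gain_range) <= 0:
            raise ValueError("window gain must be positive")
        if self.grid_cells < 1:
            raise ValueError("grid_cells must be at least 1")

    @classmethod
    def none(cls):
        """A configuration under which augmentation is the identity."""
        return cls(hflip_p=0, vflip_p=0, shift_p=0, rotate_p=0, window_p=0, grid_p=0)


def window_contrast(slice_2d: np.ndarray, gain: float) -> np.ndarray:
    """Window-width change about mid-gray: 0.5 + (x - 0.5) * gain, clamped to [0, 1]."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    return np.clip(0.5 + (np.asarray(slice_2d, dtype=np.float32) - 0.5) * gain, 0.0, 1.0)


def grid_distortion(slice_2d, mask_2d, strength: float, cells: int, rng) -> tuple:
    """Smooth per-cell displacement field warp (bilinear image, nearest mask)."""
    H, W = slice_2d.shape
    ctrl = rng.uniform(-1.0, 1.0, size=(2, cells + 1, cells + 1))
    field = np.stack([
        _sk_resize(ctrl[0], (H, W), order=1, mode="edge", preserve_range=True),
        _sk_resize(ctrl[1], (H, W), order=1, mode="edge", preserve_range=True),
    ])
    field[0] *= strength * H
    field[1] *= strength * W
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    coords = np.stack([yy + field[0], xx + field[1]])
    out_img = ndimage.map_coordinates(slice_2d, coords, order=1, mode="constant", cval=0.0)
    out_mask = ndimage.map_coordinates(mask_2d.astype(np.uint8), coords, order=0, mode="constant", cval=0)
    return out_img.astype(np.float32), out_mask.astype(np.uint8)


def apply_augmentations(slice_2d, mask_2d, config: AugmentConfig, rng) -> tuple:
    """One sampled augmentation pass over an image/mask pair.

    ``rng`` is a ``numpy.random.Generator``; a fixed state reproduces the
    augmented pair exactly. Geometric transforms are shared between image
    and mask; the mask stays binary; the image stays in [0, 1].
    """
    img = np.asarray(slice_2d, dtype=np.float32)
    mask = np.asarray(mask_2d)
    if img.shape != mask.shape:
        raise ValueError(f"shape mismatch: slice {img.shape} vs mask {mask.shape}")
    mask = mask.astype(np.uint8)

    if rng.random() < config.hflip_p:
        img, mask = img[:, ::-1], mask[:, ::-1]
    if rng.random() < config.vflip_p:
        img, mask = img[::-1, :], mask[::-1, :]
    if rng.random() < config.shift_p and config.shift_frac_max > 0:
        dy = rng.uniform(-config.shift_frac_max, config.shift_frac_max) * img.shape[0]
        dx = rng.uniform(-config.shift_frac_max, config.shift_frac_max) * img.shape[1]
        img = ndimage.shift(img, (dy, dx), order=1, mode="constant", cval=0.0)
        mask = ndimage.shift(mask, (dy, dx), order=0, mode="constant", cval=0)
    if rng.random() < config.rotate_p and config.rotate_deg_max > 0:
        angle = rng.uniform(-config.rotate_deg_max, config.rotate_deg_max)
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="constant", cval=0.0)
        mask = ndimage.rotate(mask, angle, reshape=False, order=0, mode="constant", cval=0)
    if rng.random() < config.grid_p and config.grid_distort_strength > 0:
        img, mask = grid_distortion(img, mask, config.grid_distort_strength, config.grid_cells, rng)
    if rng.random() < config.window_p:
        gain = rng.uniform(*config.window_gain_range)
        img = window_contrast(img, gain)

    return np.clip(img, 0.0, 1.0).astype(np.float32), (mask > 0).astype(np.uint8)
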
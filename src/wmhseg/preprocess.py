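"""Intensity normalization, slice resizing, and prediction restoration.

Normalization is a per-volume min-max rescale to [0, 1] — computed over the
whole 3D volume so relative lesion brightness is preserved across slices —
with no bias-field correction. A constant volume maps to all zeros rather
than raising. Optional robust percentile clipping is available but off by
default: bright artifacts do inflate the scale, and the default behaviour
deliberately leaves them in, relying on contrast augmentation at training
time instead.

Resizing uses bilinear interpolation for intensities and probabilities
(clamped, so no overshoot past the input range) and nearest-neighbour for
masks. Predictions are restored to the native grid before binarization.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize

from .io import FlairVolume

__all__ = [
    "normalize_volume",
    "resize_slice",
    "resize_mask_slice",
    "restore_prediction",
]


def normalize_volume(volume: FlairVolume, clip_percentiles=None) -> FlairVolume:
    """Min-max rescale the whole volume to [0, 1]; no bias-field correction.

    ``clip_percentiles``, if given as (lo, hi) in percent, winsorises the
    intensities before rescaling (off by default).
    """
    data = np.asarray(volume.intensities, dtype=np.float32)
    if not np.isfinite(data).all():
        raise ValueError("cannot normalize non-finite intensities")
    if clip_percentiles is not None:
        lo, hi = np.percentile(data, clip_percentiles)
        data = np.clip(data, lo, hi)
    vmin = float(data.min())
    vmax = float(data.max())
    if vmax > vmin:
        out = (data - vmin) / (vmax - vmin)
    else:
        out = np.zeros_like(data)
    return FlairVolume(out, volume.spacing_mm, volume.case_id)


def resize_slice(slice_2d: np.ndarray, target) -> np.ndarray:
    """Bilinear resize of one intensity slice; values never leave the input range."""
    slice_2d = np.asarray(slice_2d)
    if slice_2d.ndim != 2:
        raise ValueError("resize_slice expects a 2D array")
    th, tw = target
    if th < 8 or tw < 8:
        raise ValueError("target size must be at least 8x8")
    if slice_2d.shape == (th, tw):
        return slice_2d.astype(np.float32, copy=False)
    out = _sk_resize(
        slice_2d.astype(np.float32), (th, tw),
        order=1, mode="edge", anti_aliasing=False, preserve_range=True, clip=True,
    )
    return np.clip(out, slice_2d.min(), slice_2d.max()).astype(np.float32)


def resize_mask_slice(mask_2d: np.ndarray, target) -> np.ndarray:
    """Nearest-neighbour resize for binary masks (stays binary)."""
    mask_2d = np.asarray(mask_2d)
    if mask_2d.ndim != 2:
        raise ValueError("resize_mask_slice expects a 2D array")
    if mask_2d.shape == tuple(target):
        return mask_2d.astype(np.uint8, copy=False)
    out = _sk_resize(
        mask_2d.astype(np.float32), tuple(target),
        order=0, mode="edge", anti_aliasing=False, preserve_range=True,
    )
    return (out > 0.5).astype(np.uint8)


def restore_prediction(prob_slice: np.ndarray, native_shape) -> np.ndarray:
    """Map a model-resolution probability slice back to the native grid.

    Bilinear interpolation clamped to [0, 1]; binarization happens after
    restoration so evaluation runs on the native annotation grid.
    """
    prob_slice = np.asarray(prob_slice)
    if prob_slice.ndim != 2:
        raise ValueError("restore_prediction expects a 2D array")
    if prob_slice.min() < -1e-6 or prob_slice.max() > 1 + 1e-6:
        raise ValueError("probabilities must lie in [0, 1]")
    if prob_slice.shape == tuple(native_shape):
        return np.clip(prob_slice, 0.0, 1.0).astype(np.float32)
    out = _sk_resize(
        prob_slice.astype(np.float32), tuple(native_shape),
        order=1, mode="edge", anti_aliasing=False, preserve_range=True, clip=True,
    )
    return np.clip(out, 0.0, 1.0).astype(np.float32)
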
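"""Image preprocessing: ROI crop + bilinear resize, paired random-translation
augmentation of image and labels, and local contrast normalization (LCN).

The network consumes square inputs (256 px for the full model, 64 px for the
desk-scale preset).  Augmentation shifts image content and keypoint labels by
the same real-valued (dx, dy), drawn fresh per learning iteration from
Uniform[-range, range] on each axis; evaluation never augments.  LCN is the
standard subtractive + divisive normalization with per-channel box-window
statistics, which removes slow brightness/contrast variation so the network
sees appearance, not illumination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .landmarks import KeypointSet

__all__ = [
    "PreprocConfig",
    "ScaleMap",
    "crop_and_resize",
    "random_translate",
    "local_contrast_normalize",
]


@dataclass
class PreprocConfig:
    """Preprocessing parameters.

    target_size
        Side of the square network input, pixels (256 for the full model).
    translation_range
        Half-width of the uniform augmentation shift, pixels (16).
    lcn_window
        Side of the (odd) square LCN neighbourhood, pixels (19).
    lcn_epsilon
        Additive divisor regularizer; keeps flat regions finite.
    """

    target_size: int = 256
    translation_range: float = 16.0
    lcn_window: int = 19
    lcn_epsilon: float = 1e-4

    def __post_init__(self) -> None:
        if self.lcn_window % 2 != 1:
            raise ValueError("lcn_window must be odd")
        if self.translation_range < 0:
            raise ValueError("translation_range must be >= 0")


@dataclass
class ScaleMap:
    """Invertible affine map between original-image and network pixels.

    Forward: ``x_net = (x_orig - x0) * sx`` (same for y).  The image is
    resampled on exactly this grid, so transported labels and pixel content
    stay in perfect correspondence.
    """

    x0: float
    y0: float
    sx: float
    sy: float

    def to_network(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        out = np.empty_like(xy)
        out[..., 0] = (xy[..., 0] - self.x0) * self.sx
        out[..., 1] = (xy[..., 1] - self.y0) * self.sy
        return out

    def to_original(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        out = np.empty_like(xy)
        out[..., 0] = xy[..., 0] / self.sx + self.x0
        out[..., 1] = xy[..., 1] / self.sy + self.y0
        return out


def _bilinear_sample(image: np.ndarray, xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Sample ``image`` (H, W[, C]) at real coordinates, edge-clamped.

    ``xs`` and ``ys`` are 1-D axis coordinates; the sample grid is their
    outer product (separable), keeping the common resize/shift cases cheap.
    """
    h, w = image.shape[:2]
    xs = np.clip(xs, 0, w - 1)
    ys = np.clip(ys, 0, h - 1)
    x0 = np.floor(xs).astype(int)
    y0 = np.floor(ys).astype(int)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = (xs - x0).astype(image.dtype, copy=False)
    fy = (ys - y0).astype(image.dtype, copy=False)
    if image.ndim == 3:
        fx = fx[None, :, None]
        fy = fy[:, None, None]
    else:
        fx = fx[None, :]
        fy = fy[:, None]
    top = image[np.ix_(y0, x0)] * (1 - fx) + image[np.ix_(y0, x1)] * fx
    bot = image[np.ix_(y1, x0)] * (1 - fx) + image[np.ix_(y1, x1)] * fx
    return top * (1 - fy) + bot * fy


def crop_and_resize(
    image: np.ndarray, roi: tuple, target_size: int
) -> tuple[np.ndarray, ScaleMap]:
    """Crop ``roi`` = (x0, y0, width, height) and bilinearly resize to
    ``target_size`` square.  Returns the resized image and the
    :class:`ScaleMap` that transports coordinates both ways.
    """
    x0, y0, w, h = roi
    if w <= 0 or h <= 0:
        raise ValueError("roi must have positive area")
    ih, iw = image.shape[:2]
    if x0 < 0 or y0 < 0 or x0 + w > iw or y0 + h > ih:
        raise ValueError(f"roi {roi} does not fit within image of size {(iw, ih)}")
    sx = target_size / w
    sy = target_size / h
    xs = x0 + np.arange(target_size) / sx
    ys = y0 + np.arange(target_size) / sy
    out = _bilinear_sample(np.asarray(image, dtype=np.float32), xs, ys)
    return out, ScaleMap(x0=float(x0), y0=float(y0), sx=sx, sy=sy)


def random_translate(
    image: np.ndarray,
    keypoints: KeypointSet,
    range_px: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, KeypointSet]:
    """Shift image content and keypoints by the same (dx, dy).

    (dx, dy) ~ Uniform[-range_px, range_px] per axis, single-precision,
    resampled on every call.  Image content moves with the labels:
    ``out(x, y) = in(x - dx, y - dy)`` via bilinear resampling with
    edge-replicated borders.
    """
    if range_px < 0:
        raise ValueError("range_px must be >= 0")
    if range_px == 0:
        return image, keypoints
    dx, dy = rng.uniform(-range_px, range_px, size=2).astype(np.float32)
    h, w = image.shape[:2]
    xs = np.arange(w) - dx
    ys = np.arange(h) - dy
    shifted = _bilinear_sample(np.asarray(image, dtype=np.float32), xs, ys)
    return shifted, keypoints.translated(float(dx), float(dy))


def local_contrast_normalize(
    image: np.ndarray, window: int = 19, epsilon: float = 1e-4
) -> np.ndarray:
    """Per-pixel, per-channel (v - local_mean) / (local_std + epsilon).

    Statistics are taken over the ``window``-square neighbourhood of each
    pixel within its own channel, with reflected padding at the borders.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    img = np.asarray(image, dtype=np.float32)
    squeeze = img.ndim == 2
    if squeeze:
        img = img[:, :, None]
    size = (window, window, 1)
    mean = uniform_filter(img, size=size, mode="reflect")
    meansq = uniform_filter(img * img, size=size, mode="reflect")
    var = np.maximum(meansq - mean * mean, 0.0)
    out = (img - mean) / (np.sqrt(var) + np.float32(epsilon))
    if squeeze:
        out = out[:, :, 0]
    return out
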
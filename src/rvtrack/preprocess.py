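"""Frame normalization and training-time augmentation.

Frames are resampled (aspect-ratio preserving) and zero-padded to a square
network geometry, then min-max rescaled to [0, 1] per frame. Training
augmentation applies one shared geometric transform to the image and its
label map (nearest-neighbour for labels so the integer coding survives),
followed by image-only additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, resize, warp


@dataclass(frozen=True)
class AugmentationConfig:
    """Augmentation ranges: random zoom, rotation, crop, flips, noise.

    The ranges are deliberately aggressive but keep a centrally located
    annulus in frame; samples whose augmented mask loses every annular
    pixel are re-drawn rather than trained on.
    """

    zoom_range: tuple[float, float] = (0.9, 1.1)
    rotation_range: float = 15.0  # degrees, symmetric
    crop_size: int = 224
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    gaussian_noise_sigma: float = 0.01
    random_crop: bool = True  # False -> deterministic centre crop
    max_retries: int = 5

    def __post_init__(self) -> None:
        for p in (self.hflip_prob, self.vflip_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("flip probabilities must lie in [0, 1]")
        if self.zoom_range[0] <= 0 or self.zoom_range[0] > self.zoom_range[1]:
            raise ValueError("invalid zoom_range")


def standardize(frame: np.ndarray, target: int = 256):
    """Resample and zero-pad a frame to ``target`` x ``target``, rescale to [0, 1].

    The longer side is resampled to ``target`` (preserving aspect ratio) and
    the shorter side zero-padded symmetrically. Returns the standardized
    frame together with the scale factor and (row, col) pad offsets needed
    to map network-pixel coordinates back to the source grid:
    ``source = (standardized - offset) / scale``.

    A constant-intensity frame min-max rescales to all zeros (not an error).
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a nonempty 2D array")
    h, w = frame.shape
    scale = target / max(h, w)
    nh, nw = round(h * scale), round(w * scale)
    if (nh, nw) != (h, w):
        frame = resize(frame, (nh, nw), order=1, mode="edge",
                       anti_aliasing=scale < 1.0, preserve_range=True)
    pad_r = (target - nh) // 2
    pad_c = (target - nw) // 2
    out = np.zeros((target, target), dtype=float)
    out[pad_r:pad_r + nh, pad_c:pad_c + nw] = frame
    lo, hi = out.min(), out.max()
    out = (out - lo) / (hi - lo) if hi > lo else np.zeros_like(out)
    return out, scale, (pad_r, pad_c)


def _draw_transform(shape, cfg: AugmentationConfig, rng: np.random.Generator):
    h, w = shape
    zoom = rng.uniform(*cfg.zoom_range)
    angle = np.deg2rad(rng.uniform(-cfg.rotation_range, cfg.rotation_range))
    hflip = rng.random() < cfg.hflip_prob
    vflip = rng.random() < cfg.vflip_prob
    max_r = h - cfg.crop_size
    max_c = w - cfg.crop_size
    if cfg.random_crop:
        crop_r = int(rng.integers(0, max_r + 1))
        crop_c = int(rng.integers(0, max_c + 1))
    else:
        crop_r, crop_c = max_r // 2, max_c // 2
    # rotate+zoom about the image centre; skimage transforms act on (x, y)
    center = np.array([w / 2.0, h / 2.0])
    tf = (AffineTransform(translation=-center)
          + AffineTransform(rotation=angle, scale=(zoom, zoom))
          + AffineTransform(translation=center))
    return tf, hflip, vflip, (crop_r, crop_c)


def _apply(arr, tf, hflip, vflip, crop, size, order):
    out = warp(arr, tf.inverse, order=order, mode="constant", cval=0.0,
               preserve_range=True)
    r, c = crop
    out = out[r:r + size, c:c + size]
    if hflip:
        out = out[:, ::-1]
    if vflip:
        out = out[::-1, :]
    return np.ascontiguousarray(out)


def augment(
    frame: np.ndarray,
    mask: np.ndarray,
    config: AugmentationConfig,
    rng: np.random.Generator,
):
    """Jointly augment a frame and its label map.

    Returns ``(image, mask, valid)``. ``valid`` is False only when every
    re-draw (``config.max_retries``) pushed all annular pixels out of the
    crop; the trainer skips such samples instead of fitting an
    all-background target.
    """
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(mask)
    if frame.shape != mask.shape:
        raise ValueError("frame and mask must share a shape")
    if config.crop_size > min(frame.shape):
        raise ValueError("crop_size exceeds the padded frame size")

    has_annulus = (mask > 0).any()
    for _ in range(max(1, config.max_retries)):
        tf, hf, vf, crop = _draw_transform(frame.shape, config, rng)
        img_a = _apply(frame, tf, hf, vf, crop, config.crop_size, order=1)
        mask_a = _apply(mask.astype(float), tf, hf, vf, crop,
                        config.crop_size, order=0).astype(mask.dtype)
        if config.gaussian_noise_sigma > 0:
            img_a = img_a + rng.normal(0.0, config.gaussian_noise_sigma, img_a.shape)
        if not has_annulus or (mask_a > 0).any():
            return img_a, mask_a, True
    return img_a, mask_a, False
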
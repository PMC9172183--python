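"""Paired 2D data augmentation for segmentation training.

Geometric transforms (flips, rotation, scaling) are applied identically to
image and mask — the mask with nearest-neighbour resampling so it stays
binary — while intensity transforms (blur, additive noise) touch the image
only. Everything is driven by one seeded generator, so the same seed yields
the same augmented pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentationConfig", "augment_pair"]


@dataclass(frozen=True)
class AugmentationConfig:
    """Augmentation switches and ranges.

    ``target_resolution_mm`` records the in-plane resolution the training
    slices are resampled to before augmentation (the recipe calls for a
    consistent 1–1.5 mm grid); the slice generator owns the resampling, the
    value is carried here for provenance.
    """

    flips: bool = True
    rotate_deg: float = 10.0
    scale_range: tuple[float, float] = (0.95, 1.05)
    blur_sigma_max: float = 0.7
    noise_sd_max: float = 0.02
    target_resolution_mm: float = 1.3125

    def __post_init__(self):
        if not 1.0 <= self.target_resolution_mm <= 1.5:
            raise ValueError("target resolution must lie in [1, 1.5] mm")


def _identity(cfg: AugmentationConfig) -> bool:
    return (not cfg.flips and cfg.rotate_deg == 0
            and cfg.scale_range == (1.0, 1.0)
            and cfg.blur_sigma_max == 0 and cfg.noise_sd_max == 0)


def augment_pair(image: np.ndarray, mask: np.ndarray,
                 config: AugmentationConfig | None = None,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Randomly augment one image/mask slice pair (deterministic per seed)."""
    config = config or AugmentationConfig()
    img = np.asarray(image, dtype=np.float64)
    msk = np.asarray(mask, dtype=bool)
    if img.shape != msk.shape or img.ndim != 2:
        raise ValueError("image and mask must be 2D arrays on the same grid")
    if _identity(config):
        return img.copy(), msk.copy()

    rng = np.random.default_rng(seed)
    if config.flips:
        if rng.random() < 0.5:
            img, msk = img[::-1], msk[::-1]
        if rng.random() < 0.5:
            img, msk = img[:, ::-1], msk[:, ::-1]

    angle = float(rng.uniform(-config.rotate_deg, config.rotate_deg))
    if angle != 0.0:
        img = ndimage.rotate(img, angle, reshape=False, order=1, mode="nearest")
        msk = ndimage.rotate(msk.astype(np.uint8), angle, reshape=False,
                             order=0, mode="constant") > 0

    lo, hi = config.scale_range
    scale = float(rng.uniform(lo, hi))
    if scale != 1.0:
        H, W = img.shape
        center = (np.asarray(img.shape) - 1) / 2.0
        # resample about the center at the inverse zoom, keeping the grid size
        mat = np.eye(2) / scale
        offset = center - mat @ center
        img = ndimage.affine_transform(img, mat, offset=offset, order=1,
                                       mode="nearest")
        msk = ndimage.affine_transform(msk.astype(np.uint8), mat, offset=offset,
                                       order=0, mode="constant") > 0

    sigma = float(rng.uniform(0.0, config.blur_sigma_max))
    if sigma > 0:
        img = ndimage.gaussian_filter(img, sigma)
    noise_sd = float(rng.uniform(0.0, config.noise_sd_max))
    if noise_sd > 0:
        scale_ref = np.abs(img).max() or 1.0
        img = img + rng.normal(0.0, noise_sd * scale_ref, size=img.shape)

    return np.ascontiguousarray(img), np.ascontiguousarray(msk)
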
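"""Deterministic train-time augmentations and input preprocessing.

The stack mirrors a typical medical-segmentation augmentation recipe: random
flips, additive Gaussian noise, Gaussian blurring, and affine and elastic
deformations, applied in that fixed order with independent per-transform
probabilities.  Geometric transforms move image and mask identically — the
image with bilinear interpolation, the mask with nearest-neighbour so it stays
binary; intensity transforms touch the image only.

Every draw is a pure function of ``(config.seed, draw_index)``, so an epoch's
augmentations can be replayed bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .core import ConfigurationError, ImageFrame, SegMask, _require_same_grid

__all__ = ["AugmentConfig", "preprocess", "augment_pair", "PREPROCESS_MEAN", "PREPROCESS_STD"]

PREPROCESS_MEAN = 0.456
PREPROCESS_STD = 0.224
_TARGET_SIZE = (256, 256)


@dataclass(frozen=True)
class AugmentConfig:
    """Probabilities and magnitudes of the augmentation stack.

    Each transform fires independently with its probability; magnitudes are
    drawn uniformly from the stated ranges.  Defaults are moderate values in
    the range a segmentation pipeline would use; all are configurable.
    """

    flip_prob: float = 0.5
    noise_prob: float = 0.5
    noise_sd: float = 0.05
    blur_prob: float = 0.5
    blur_sigma_range: tuple[float, float] = (0.5, 1.5)
    affine_prob: float = 0.5
    rotation_range_deg: float = 15.0
    scale_range: tuple[float, float] = (0.9, 1.1)
    translation_range_px: float = 10.0
    elastic_prob: float = 0.5
    elastic_grid_px: float = 32.0
    elastic_sd_px: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("flip_prob", "noise_prob", "blur_prob", "affine_prob", "elastic_prob"):
            p = getattr(self, name)
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
        if self.noise_sd < 0 or self.elastic_sd_px < 0 or self.translation_range_px < 0:
            raise ConfigurationError("spreads must be >= 0")
        if self.blur_sigma_range[0] < 0 or self.blur_sigma_range[1] < self.blur_sigma_range[0]:
            raise ConfigurationError(f"invalid blur_sigma_range {self.blur_sigma_range}")
        if self.elastic_grid_px <= 0:
            raise ConfigurationError("elastic_grid_px must be positive")


def preprocess(image: ImageFrame) -> ImageFrame:
    """Network input preprocessing: bilinear resize to 256x256, then
    standardisation ``(x - 0.456) / 0.224``.

    Images already at 256x256 are normalised without resampling.
    """
    data = image.data
    if data.shape != _TARGET_SIZE:
        data = resize(data, _TARGET_SIZE, order=1, anti_aliasing=False, preserve_range=True)
    return ImageFrame((data - PREPROCESS_MEAN) / PREPROCESS_STD, image.spacing_mm)


def _affine_params(rng: np.random.Generator, config: AugmentConfig):
    angle = rng.uniform(-config.rotation_range_deg, config.rotation_range_deg)
    scale = rng.uniform(*config.scale_range)
    shift = rng.uniform(-config.translation_range_px, config.translation_range_px, size=2)
    return angle, scale, shift


def _apply_affine(arr: np.ndarray, angle: float, scale: float, shift: np.ndarray, order: int, cval: float) -> np.ndarray:
    theta = np.deg2rad(angle)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    matrix = rot / scale  # output->input mapping
    center = (np.asarray(arr.shape, dtype=np.float64) - 1) / 2.0
    offset = center - matrix @ (center + shift)
    return ndimage.affine_transform(arr, matrix, offset=offset, order=order, mode="constant", cval=cval)


def _elastic_field(rng: np.random.Generator, shape: tuple[int, int], config: AugmentConfig) -> np.ndarray:
    # coarse random displacement grid, spline-upsampled to the full image
    n_r = max(int(np.ceil(shape[0] / config.elastic_grid_px)) + 1, 2)
    n_c = max(int(np.ceil(shape[1] / config.elastic_grid_px)) + 1, 2)
    coarse = rng.normal(0.0, config.elastic_sd_px, size=(2, n_r, n_c))
    field = np.empty((2,) + shape)
    for d in range(2):
        field[d] = ndimage.zoom(coarse[d], (shape[0] / n_r, shape[1] / n_c), order=3)
    return field


def _apply_displacement(arr: np.ndarray, field: np.ndarray, order: int, cval: float) -> np.ndarray:
    rr, cc = np.meshgrid(np.arange(arr.shape[0]), np.arange(arr.shape[1]), indexing="ij")
    coords = np.stack([rr + field[0], cc + field[1]])
    return ndimage.map_coordinates(arr, coords, order=order, mode="constant", cval=cval)


def augment_pair(
    image: ImageFrame,
    mask: SegMask,
    config: AugmentConfig,
    draw_index: int = 0,
) -> tuple[ImageFrame, SegMask]:
    """One stochastic augmentation draw applied jointly to an image/mask pair.

    Transforms fire in the fixed order flip, noise, blur, affine, elastic.
    The random stream is fully determined by ``(config.seed, draw_index)``;
    repeated calls with the same pair of values are bit-identical, different
    ``draw_index`` values give independent draws.
    """
    _require_same_grid(image, mask)
    rng = np.random.default_rng([abs(int(config.seed)), abs(int(draw_index))])
    img = image.data.copy()
    msk = mask.data.astype(np.float64)

    if rng.random() < config.flip_prob:
        axis = int(rng.integers(0, 2))
        img = np.flip(img, axis=axis)
        msk = np.flip(msk, axis=axis + 1)
    if rng.random() < config.noise_prob and config.noise_sd > 0:
        img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
    if rng.random() < config.blur_prob:
        sigma = rng.uniform(*config.blur_sigma_range)
        if sigma > 0:
            img = ndimage.gaussian_filter(img, sigma)
    if rng.random() < config.affine_prob:
        angle, scale, shift = _affine_params(rng, config)
        img = _apply_affine(img, angle, scale, shift, order=1, cval=0.0)
        msk = np.stack([_apply_affine(ch, angle, scale, shift, order=0, cval=0.0) for ch in msk])
    if rng.random() < config.elastic_prob:
        field = _elastic_field(rng, img.shape, config)
        img = _apply_displacement(img, field, order=1, cval=0.0)
        msk = np.stack([_apply_displacement(ch, field, order=0, cval=0.0) for ch in msk])

    out_mask = SegMask((msk > 0.5).astype(np.uint8), mask.spacing_mm)
    return ImageFrame(np.ascontiguousarray(img), image.spacing_mm), out_mask
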
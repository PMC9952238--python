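"""Boundary-aware shape loss and combined segmentation loss, as evaluable functions.

The shape loss compares a soft prediction against the *shape information* map
of the ground truth: a sigmoid-softened function of the signed normalized
Euclidean distance map that peaks just inside the mask boundary and is zero
outside.  Penalising the pixel-wise deviation from this map weights boundary
pixels far more heavily than the deep interior, which is where segmentation
quality is won or lost.

All quantities are plain functions of ``(g, p)`` arrays — no autograd, no
training loop.  Masks are ``(C, H, W)`` (a 2D array is treated as a single
channel); ``g`` is binary, ``p`` is a soft prediction in [0, 1] (e.g. the
sigmoid of network log-odds).

The combined loss is

    L(g, p) = (1 - soft Dice) + cross-entropy + gamma * L_S(g, p)

with the soft Dice and cross-entropy terms averaged over channels and the
shape term weighted by ``gamma`` (default 0.05); the boundary softness ``k``
defaults to 0.2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .core import ConfigurationError, DataError, DegenerateMaskError

__all__ = [
    "LossConfig",
    "boundary_sigmoid",
    "signed_distance_map",
    "shape_information",
    "shape_loss",
    "soft_dice_term",
    "cross_entropy_loss",
    "combined_loss",
]


@dataclass(frozen=True)
class LossConfig:
    """Loss hyper-parameters: boundary softness ``k``, shape-loss weight
    ``gamma`` and the numerical floor ``epsilon`` for logs and divisions."""

    k: float = 0.2
    gamma: float = 0.05
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ConfigurationError(f"k must be > 0, got {self.k}")
        if self.gamma < 0:
            raise ConfigurationError(f"gamma must be >= 0, got {self.gamma}")
        if self.epsilon <= 0:
            raise ConfigurationError(f"epsilon must be > 0, got {self.epsilon}")


def _as_channels(arr: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(arr, dtype=np.float64)
    if a.ndim == 2:
        a = a[np.newaxis]
    if a.ndim != 3:
        raise DataError(f"{name} must be 2D or (C, H, W), got shape {a.shape}")
    return a


def _check_pair(g: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g = _as_channels(g, "ground truth")
    p = _as_channels(p, "prediction")
    if g.shape != p.shape:
        raise DataError(f"ground truth {g.shape} and prediction {p.shape} shapes differ")
    return g, p


def boundary_sigmoid(x: np.ndarray | float, k: float = 0.2) -> np.ndarray | float:
    """Softened step ``H(x) = 1 / (1 + exp(-x/k))``; ``k`` sets boundary softness."""
    if k <= 0:
        raise ConfigurationError(f"k must be > 0, got {k}")
    return expit(np.asarray(x, dtype=np.float64) / k)


def signed_distance_map(mask_channel: np.ndarray) -> np.ndarray:
    """Signed normalized Euclidean distance map of one binary channel.

    Raw value: +distance to the nearest background pixel on foreground,
    -distance to the nearest foreground pixel on background, measured between
    pixel centres (a foreground pixel adjacent to background has raw value 1).
    The result is divided by its maximum absolute value, so the range is
    [-1, 1] with the extreme reached somewhere in the image.
    """
    m = np.asarray(mask_channel)
    fg = m > 0
    if fg.all() or not fg.any():
        raise DegenerateMaskError("distance map requires both foreground and background pixels")
    raw = np.where(fg, ndimage.distance_transform_edt(fg), -ndimage.distance_transform_edt(~fg))
    return raw / np.abs(raw).max()


def shape_information(mask_channel: np.ndarray, k: float = 0.2) -> np.ndarray:
    """Shape-information map SI(m) = H(1 - phi(m)) on foreground, 0 on background.

    ``phi`` is the signed normalized distance map (positive inside).  SI peaks
    near H(1) at foreground pixels closest to the boundary and decays toward
    H(0) = 0.5 in the deep interior; it is exactly 0 outside the mask.
    """
    phi = signed_distance_map(mask_channel)
    return np.where(phi >= 0, boundary_sigmoid(1.0 - phi, k), 0.0)


def shape_loss(g: np.ndarray, p: np.ndarray, k: float = 0.2) -> float:
    """Boundary-aware shape loss L_S(g, p).

    Per channel, the mean absolute deviation of the prediction from SI(g),
    summed over all pixels and normalised by the channel's foreground size;
    averaged over channels.  Zero iff the prediction equals the
    shape-information map everywhere.
    """
    g, p = _check_pair(g, p)
    total = 0.0
    for gc, pc in zip(g, p):
        fg_size = gc.sum()
        if fg_size == 0:
            raise DegenerateMaskError("shape_loss requires a non-empty ground-truth channel")
        si = shape_information(gc, k)
        total += float(np.abs(pc - si).sum()) / float(fg_size)
    return total / g.shape[0]


def soft_dice_term(g: np.ndarray, p: np.ndarray, epsilon: float = 1e-6) -> float:
    """Channel-averaged soft Dice overlap term ``(2*sum(g*p)+eps)/(sum(g)+sum(p)+eps)``.

    This is the overlap term itself (1 for a perfect match); the loss
    contribution in the combined loss is one minus it.
    """
    g, p = _check_pair(g, p)
    num = 2.0 * (g * p).sum(axis=(1, 2)) + epsilon
    den = g.sum(axis=(1, 2)) + p.sum(axis=(1, 2)) + epsilon
    return float(np.mean(num / den))


def cross_entropy_loss(g: np.ndarray, p: np.ndarray, epsilon: float = 1e-6) -> float:
    """Pixel-wise cross entropy ``-(1/C) sum_c sum_i g * log(max(p, eps))``."""
    g, p = _check_pair(g, p)
    return float(-(g * np.log(np.clip(p, epsilon, None))).sum() / g.shape[0])


def combined_loss(g: np.ndarray, p: np.ndarray, config: LossConfig | None = None) -> float:
    """Full segmentation loss: ``(1 - soft Dice) + cross-entropy + gamma * L_S``.

    With ``gamma = 0`` this reduces exactly to the equally weighted
    Dice-plus-cross-entropy loss.
    """
    if config is None:
        config = LossConfig()
    loss = (1.0 - soft_dice_term(g, p, config.epsilon)) + cross_entropy_loss(g, p, config.epsilon)
    if config.gamma > 0:
        loss += config.gamma * shape_loss(g, p, config.k)
    return loss
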
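"""Shared containers for 2D short-axis images and segmentation masks.

The package works on single 2D slices: an :class:`ImageFrame` holds a scalar
intensity grid plus pixel spacing in millimetres, a :class:`SegMask` holds one
or more binary label planes over the same grid.  Both are thin, validated
wrappers around numpy arrays; all numerical work happens on ``.data``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ImageFrame", "SegMask", "ConfigurationError", "DataError", "DegenerateMaskError"]


class ConfigurationError(ValueError):
    """Invalid parameter value (spacing, flip angle, radii, ...)."""


class DataError(ValueError):
    """Inconsistent or malformed input data (grid mismatch, negative intensities, ...)."""


class DegenerateMaskError(DataError):
    """A mask channel is all-foreground or all-background where a boundary is required."""


@dataclass(frozen=True)
class ImageFrame:
    """A 2D grayscale image with physical pixel spacing.

    Parameters
    ----------
    data
        2D float array of intensities.
    spacing_mm
        Pixel size as ``(row_mm, col_mm)``.  Defaults to isotropic 1 mm.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim != 2:
            raise DataError(f"ImageFrame requires a 2D array, got shape {arr.shape}")
        object.__setattr__(self, "data", arr)
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != 2 or any(s <= 0 for s in sp):
            raise ConfigurationError(f"spacing_mm must be two positive values, got {self.spacing_mm}")
        object.__setattr__(self, "spacing_mm", sp)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class SegMask:
    """A multi-channel binary segmentation mask.

    ``data`` is stored as ``(C, H, W)`` uint8 with values in {0, 1}; a plain
    2D array is promoted to a single channel.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim == 2:
            arr = arr[np.newaxis]
        if arr.ndim != 3:
            raise DataError(f"SegMask requires a 2D or (C, H, W) array, got shape {arr.shape}")
        uniq = np.unique(arr)
        if not np.isin(uniq, (0, 1)).all():
            raise DataError(f"SegMask values must be binary, found {uniq[:10]}")
        object.__setattr__(self, "data", arr.astype(np.uint8))
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != 2 or any(s <= 0 for s in sp):
            raise ConfigurationError(f"spacing_mm must be two positive values, got {self.spacing_mm}")
        object.__setattr__(self, "spacing_mm", sp)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial (H, W) shape."""
        return self.data.shape[1:]  # type: ignore[return-value]

    def channel(self, c: int = 0) -> np.ndarray:
        return self.data[c]


def _require_same_grid(image: ImageFrame, mask: SegMask) -> None:
    if image.shape != mask.shape:
        raise DataError(f"image grid {image.shape} does not match mask grid {mask.shape}")
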
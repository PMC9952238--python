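"""Dataset-level orchestration: read annotated cine datasets, transform every
slice into its tagged-appearing counterpart with the segmentation mask
transferred unchanged, and write the result with a CSV manifest.

Two on-disk layouts are supported:

``nifti-acdc``
    Per-subject NIfTI volumes with a ``_gt`` companion label volume
    (``patient001.nii.gz`` + ``patient001_gt.nii.gz``); 3D volumes are read
    slice-by-slice, 4D volumes frame-by-frame per slice.  The myocardium
    channel is extracted from the label volume by a configurable label index
    (ACDC convention: myocardium = 2).

``png-pairs``
    Flat directories of 8-bit grayscale PNGs, ``<id>.png`` with companion
    ``<id>_mask.png``.

The transformation itself lives in :mod:`cine2tag.tagsim`; this module is
plumbing around it.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterator

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from .core import DataError, ImageFrame, SegMask
from .phantom import PhantomConfig, generate_phantom_series
from .tagsim import TagPrepConfig, transform_cine_to_tagged

__all__ = [
    "DatasetManifest",
    "read_slice_pairs",
    "transform_dataset",
    "write_phantom_dataset",
    "save_pair_png",
    "load_mask",
]

logger = logging.getLogger(__name__)

MYO_LABEL_ACDC = 2


@dataclass
class DatasetManifest:
    """Record of a transformation run: one row per slice plus the parameter hash."""

    records: pd.DataFrame
    params_hash: str

    def __len__(self) -> int:
        return len(self.records)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def _config_hash(config: TagPrepConfig) -> str:
    return hashlib.sha256(repr(sorted(asdict(config).items())).encode()).hexdigest()[:12]


def _load_png_image(path: Path) -> np.ndarray:
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:  # collapse any color channels
        arr = arr[..., 0]
    return arr.astype(np.float64) / 255.0


def load_mask(path: Path, myo_label: int | None = None) -> np.ndarray:
    """Read a binary (or labelled) mask from PNG or NIfTI as a 2D 0/1 array."""
    path = Path(path)
    if path.suffix == ".png":
        arr = np.asarray(iio.imread(path))
        if arr.ndim == 3:
            arr = arr[..., 0]
    else:
        arr = np.asarray(nib.load(str(path)).dataobj)
        arr = np.squeeze(arr)
        if arr.ndim != 2:
            raise DataError(f"expected a 2D mask in {path}, got shape {arr.shape}")
    if myo_label is not None:
        return (arr == myo_label).astype(np.uint8)
    return (arr > 0).astype(np.uint8)


def _nifti_spacing(img: nib.spatialimages.SpatialImage) -> tuple[float, float]:
    zooms = img.header.get_zooms()
    if len(zooms) >= 2 and zooms[0] > 0 and zooms[1] > 0:
        return (float(zooms[0]), float(zooms[1]))
    return (1.0, 1.0)


def _iter_nifti_pairs(path: Path, myo_label: int | None) -> Iterator[tuple[ImageFrame, SegMask, dict]]:
    images = sorted(p for p in path.glob("*.nii*") if "_gt" not in p.name and "_mask" not in p.name)
    if not images:
        raise DataError(f"no NIfTI images found under {path}")
    for img_path in images:
        stem = img_path.name.split(".nii")[0]
        gt_path = None
        for suffix in (".nii.gz", ".nii"):
            cand = img_path.with_name(f"{stem}_gt{suffix}")
            if cand.exists():
                gt_path = cand
                break
        if gt_path is None:
            raise DataError(f"missing '_gt' companion label volume for {img_path.name}")
        img_nii = nib.load(str(img_path))
        gt_nii = nib.load(str(gt_path))
        spacing = _nifti_spacing(img_nii)
        img_data = np.asarray(img_nii.dataobj, dtype=np.float64)
        gt_data = np.asarray(gt_nii.dataobj)
        if img_data.shape != gt_data.shape:
            raise DataError(f"image/label shape mismatch for {img_path.name}")
        if img_data.ndim == 2:
            img_data = img_data[..., np.newaxis]
            gt_data = gt_data[..., np.newaxis]
        if img_data.ndim == 3:
            img_data = img_data[..., np.newaxis]
            gt_data = gt_data[..., np.newaxis]
        n_slices, n_frames = img_data.shape[2], img_data.shape[3]
        for z in range(n_slices):
            for t in range(n_frames):
                plane = img_data[:, :, z, t]
                labels = gt_data[:, :, z, t]
                myo = (labels == myo_label) if myo_label is not None else (labels > 0)
                meta = {"subject": stem, "slice": z, "frame": t, "source": img_path.name}
                yield ImageFrame(plane, spacing), SegMask(myo.astype(np.uint8), spacing), meta


def _iter_png_pairs(path: Path) -> Iterator[tuple[ImageFrame, SegMask, dict]]:
    images = sorted(p for p in path.glob("*.png") if not p.stem.endswith("_mask"))
    if not images:
        raise DataError(f"no PNG images found under {path}")
    for img_path in images:
        mask_path = img_path.with_name(f"{img_path.stem}_mask.png")
        if not mask_path.exists():
            raise DataError(f"missing companion mask for {img_path.name}")
        image = ImageFrame(_load_png_image(img_path))
        mask = SegMask(load_mask(mask_path))
        meta = {"subject": img_path.stem, "slice": 0, "frame": 0, "source": img_path.name}
        yield image, mask, meta


def read_slice_pairs(
    path,
    format: str = "png-pairs",
    myo_label: int | None = None,
) -> Iterator[tuple[ImageFrame, SegMask, dict]]:
    """Yield (image, mask, metadata) slice pairs from an annotated dataset.

    ``format`` is ``"nifti-acdc"`` (image + ``_gt`` label companion volumes)
    or ``"png-pairs"`` (``<id>.png`` + ``<id>_mask.png``).  ``myo_label``
    selects one label index from multi-label volumes (ACDC myocardium = 2);
    None binarises all nonzero labels.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"input path does not exist: {path}")
    if format == "nifti-acdc":
        yield from _iter_nifti_pairs(path, myo_label)
    elif format == "png-pairs":
        yield from _iter_png_pairs(path)
    else:
        raise DataError(f"unknown format {format!r}; use 'nifti-acdc' or 'png-pairs'")


def save_pair_png(image: ImageFrame, mask: SegMask, img_path: Path, mask_path: Path) -> None:
    """Write an image/mask pair as 8-bit grayscale PNGs."""
    iio.imwrite(img_path, np.clip(np.round(image.data * 255.0), 0, 255).astype(np.uint8))
    iio.imwrite(mask_path, (mask.channel(0) * 255).astype(np.uint8))


def transform_dataset(
    input_path,
    output_path,
    tag_config: TagPrepConfig | None = None,
    format: str = "png-pairs",
    myo_label: int | None = None,
) -> DatasetManifest:
    """Transform every slice of a cine dataset into its tagged-appearing twin.

    Writes ``<subject>_f<frame>.png`` + ``_mask.png`` pairs under
    ``output_path`` plus ``manifest.csv``; masks are copied bit-identically
    from the input.  Deterministic: re-running with the same config rewrites
    identical outputs.
    """
    if tag_config is None:
        tag_config = TagPrepConfig()
    output_path = Path(output_path)
    output_path.mkdir(parents=True, exist_ok=True)
    params_hash = _config_hash(tag_config)
    logger.info("transform run: config=%s hash=%s", tag_config, params_hash)

    rows = []
    for image, mask, meta in read_slice_pairs(input_path, format=format, myo_label=myo_label):
        tagged, out_mask = transform_cine_to_tagged(image, mask, frame_index=meta.get("frame", 0), config=tag_config)
        stem = f"{meta['subject']}_s{meta['slice']:02d}_f{meta['frame']:02d}"
        img_out = output_path / f"{stem}.png"
        mask_out = output_path / f"{stem}_mask.png"
        try:
            save_pair_png(tagged, out_mask, img_out, mask_out)
        except OSError:
            img_out.unlink(missing_ok=True)
            mask_out.unlink(missing_ok=True)
            raise
        rows.append(
            {
                "subject": meta["subject"],
                "slice": meta["slice"],
                "frame": meta["frame"],
                "image_path": str(img_out),
                "mask_path": str(mask_out),
                "params_hash": params_hash,
            }
        )
    manifest = DatasetManifest(pd.DataFrame(rows), params_hash)
    manifest.to_csv(output_path / "manifest.csv")
    return manifest


def write_phantom_dataset(
    output_path,
    n_subjects: int = 2,
    config: PhantomConfig | None = None,
) -> pd.DataFrame:
    """Generate a synthetic phantom dataset on disk.

    Writes per-frame PNG image/mask pairs and one 2D+t NIfTI volume pair per
    subject (image + ``_gt`` labels), plus ``manifest.csv``.  Subjects differ
    by seed only.
    """
    if config is None:
        config = PhantomConfig()
    output_path = Path(output_path)
    output_path.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in range(n_subjects):
        sub_cfg = PhantomConfig(**{**asdict(config), "seed": config.seed + s})
        subject = f"subject{s:03d}"
        series = generate_phantom_series(sub_cfg)
        img_vol = np.stack([f.data for f, _ in series], axis=-1)[:, :, np.newaxis, :]
        gt_vol = np.stack([m.channel(0) for _, m in series], axis=-1)[:, :, np.newaxis, :]
        nib.save(nib.Nifti1Image(img_vol.astype(np.float32), np.eye(4)), str(output_path / f"{subject}.nii.gz"))
        nib.save(nib.Nifti1Image(gt_vol.astype(np.uint8), np.eye(4)), str(output_path / f"{subject}_gt.nii.gz"))
        for t, (frame, mask) in enumerate(series):
            stem = f"{subject}_f{t:02d}"
            save_pair_png(frame, mask, output_path / f"{stem}.png", output_path / f"{stem}_mask.png")
            rows.append(
                {
                    "subject": subject,
                    "frame": t,
                    "image_path": str(output_path / f"{stem}.png"),
                    "mask_path": str(output_path / f"{stem}_mask.png"),
                }
            )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(output_path / "manifest.csv", index=False)
    return manifest
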
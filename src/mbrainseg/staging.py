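"""Data staging: resampling, center-of-mass cropping, padding, normalization.

Raw acquisitions differ in voxel spacing and matrix size; whole-image network
training requires a uniform grid.  Staging therefore (1) resamples every
volume to a target spacing, (2) crops/pads a window of fixed shape centred on
the image centre of mass, and (3) Z-score normalizes intensities.  Masks ride
along through the same geometric operations (nearest-neighbour, COM taken
from the image) and are never normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .volumes import LabelMask, Volume, read_nifti, write_nifti

__all__ = [
    "StagingConfig",
    "resample",
    "center_of_mass",
    "crop_pad_to_shape",
    "zscore_normalize",
    "stage_pair",
    "stage_dataset",
]


@dataclass
class StagingConfig:
    target_spacing: tuple[float, float, float] = (0.20, 0.20, 0.40)
    target_shape: tuple[int, int, int] = (64, 64, 32)
    image_interpolation_order: int = 1
    # mask interpolation is fixed nearest-neighbour

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.target_spacing):
            raise ValueError("target_spacing must be positive")
        if any(n < 8 for n in self.target_shape):
            raise ValueError("target_shape dims must each be >= 8")

    def validate_for_depth(self, depth: int) -> None:
        """Training requires each dim divisible by 2**(depth-1)."""
        div = 2 ** (depth - 1)
        if any(n % div for n in self.target_shape):
            raise ValueError(
                f"target_shape {self.target_shape} not divisible by {div} "
                f"(network depth {depth})"
            )


def resample(vol: Volume | LabelMask, target_spacing) -> Volume | LabelMask:
    """Resample to ``target_spacing``; linear for images, nearest for masks."""
    target_spacing = tuple(float(s) for s in target_spacing)
    if any(s <= 0 for s in target_spacing):
        raise ValueError("target spacing must be strictly positive")
    in_shape = np.asarray(vol.shape)
    in_sp = np.asarray(vol.spacing)
    out_shape = np.maximum(np.round(in_shape * in_sp / np.asarray(target_spacing)), 1).astype(int)
    zoom = out_shape / in_shape
    if isinstance(vol, LabelMask):
        data = ndi.zoom(vol.data, zoom, order=0, mode="nearest", grid_mode=True)
        data = data[: out_shape[0], : out_shape[1], : out_shape[2]]
        return LabelMask(data, target_spacing, vol.origin, labels=dict(vol.labels))
    data = ndi.zoom(vol.data.astype(np.float32), zoom, order=1, mode="nearest", grid_mode=True)
    data = data[: out_shape[0], : out_shape[1], : out_shape[2]]
    return Volume(data, target_spacing, vol.origin)


def center_of_mass(vol: Volume) -> tuple[float, float, float]:
    """Intensity-weighted mean voxel index.

    Negative-valued inputs (e.g. already Z-scored data) are shifted so the
    minimum sits at zero before weighting; non-negative inputs are used
    as-is, so a uniform positive volume yields its geometric centre.
    """
    data = vol.data.astype(np.float64)
    data = data - min(float(data.min()), 0.0)
    total = data.sum()
    if total <= 0:
        raise ValueError("center of mass undefined: volume has no intensity above its minimum")
    return tuple(float(c) for c in ndi.center_of_mass(data))


def crop_pad_to_shape(vol: Volume | LabelMask, target_shape, center) -> Volume | LabelMask:
    """Extract a window of ``target_shape`` centred (rounded) on ``center``.

    Where the window exceeds the grid it is zero-padded, so the output shape
    is exactly ``target_shape``.  Idempotent when re-applied with the output's
    own geometric centre.
    """
    target_shape = tuple(int(n) for n in target_shape)
    if any(n < 1 for n in target_shape):
        raise ValueError("target_shape dims must be >= 1")
    data = vol.data
    out = np.zeros(target_shape, dtype=data.dtype)
    src_slices, dst_slices = [], []
    for ax in range(3):
        c = int(np.floor(float(center[ax]) + 0.5))  # round half up, so a geometric center maps to an identity window
        start = c - target_shape[ax] // 2
        stop = start + target_shape[ax]
        src_lo, src_hi = max(start, 0), min(stop, data.shape[ax])
        if src_lo >= src_hi:  # window entirely outside the grid
            src_slices.append(slice(0, 0))
            dst_slices.append(slice(0, 0))
            continue
        src_slices.append(slice(src_lo, src_hi))
        dst_slices.append(slice(src_lo - start, src_hi - start))
    out[tuple(dst_slices)] = data[tuple(src_slices)]
    if isinstance(vol, LabelMask):
        return LabelMask(out, vol.spacing, vol.origin, labels=dict(vol.labels))
    return Volume(out, vol.spacing, vol.origin)


def zscore_normalize(vol: Volume) -> Volume:
    """Zero-mean unit-variance intensities over all voxels."""
    data = vol.data.astype(np.float64)
    std = data.std()
    if std == 0:
        raise ValueError("zero variance: cannot Z-score a constant volume")
    return Volume(((data - data.mean()) / std).astype(np.float32), vol.spacing, vol.origin)


def stage_pair(
    image: Volume,
    mask: LabelMask | None,
    config: StagingConfig,
    normalize: bool = True,
) -> tuple[Volume, LabelMask | None]:
    """Stage one image (and optionally its mask) with a shared geometry."""
    if mask is not None and mask.shape != image.shape:
        raise ValueError(f"image/mask shape mismatch: {image.shape} vs {mask.shape}")
    img = resample(image, config.target_spacing)
    com = center_of_mass(img)
    img = crop_pad_to_shape(img, config.target_shape, com)
    if normalize:
        img = zscore_normalize(img)
    staged_mask = None
    if mask is not None:
        m = resample(mask, config.target_spacing)
        staged_mask = crop_pad_to_shape(m, config.target_shape, com)
    return img, staged_mask


def stage_dataset(input_dir, output_dir, config: StagingConfig, normalize: bool = True) -> pd.DataFrame:
    """Stage every image(/mask) pair found in ``input_dir``.

    Pairs are taken from ``manifest.csv`` when present, otherwise matched by
    the ``img_*``/``msk_*`` naming convention.  Writes staged NIfTI pairs and
    a ``staging_log.csv`` with per-file provenance.
    """
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = input_dir / "manifest.csv"
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path)
        pairs = [(input_dir / r["image"], input_dir / r["mask"] if isinstance(r.get("mask"), str) else None)
                 for _, r in manifest.iterrows()]
    else:
        images = sorted(input_dir.glob("img_*.nii*"))
        if not images:
            raise FileNotFoundError(f"no manifest.csv or img_* files in {input_dir}")
        pairs = []
        for img_path in images:
            msk_path = img_path.with_name(img_path.name.replace("img_", "msk_"))
            pairs.append((img_path, msk_path if msk_path.exists() else None))
    rows = []
    for img_path, msk_path in pairs:
        image = read_nifti(img_path)
        mask = read_nifti(msk_path, as_mask=True) if msk_path else None
        staged_img, staged_mask = stage_pair(image, mask, config, normalize=normalize)
        write_nifti(staged_img, output_dir / img_path.name)
        if staged_mask is not None:
            write_nifti(staged_mask, output_dir / msk_path.name)
        rows.append(
            {
                "image": img_path.name,
                "mask": msk_path.name if msk_path else "",
                "input_shape": str(image.shape),
                "input_spacing": str(tuple(round(s, 6) for s in image.spacing)),
                "staged_shape": str(staged_img.shape),
                "staged_spacing": str(tuple(round(s, 6) for s in staged_img.spacing)),
                "normalized": normalize,
            }
        )
    log = pd.DataFrame(rows)
    log.to_csv(output_dir / "staging_log.csv", index=False)
    return log
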
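"""Post-segmentation cleanup and quantification.

Network predictions occasionally contain small disconnected fragments and
interior holes; anatomically a whole-brain mask is a single solid component.
This module removes fragments by connected-component analysis, fills holes,
computes region volumes in mm^3, and applies a brain mask to an image
(skull stripping proper).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .volumes import LabelMask, Volume

__all__ = [
    "PostprocessConfig",
    "remove_fragments",
    "fill_holes",
    "compute_volume",
    "apply_brain_mask",
    "postprocess_mask",
]


@dataclass
class PostprocessConfig:
    mode: str = "keep_largest"  # or "min_size_threshold"
    min_size: int = 1
    fill_holes: bool = True
    connectivity: int = 26  # component analysis; hole filling uses 6

    def __post_init__(self) -> None:
        if self.mode not in ("keep_largest", "min_size_threshold"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")


def _structure(connectivity: int) -> np.ndarray:
    return ndi.generate_binary_structure(3, 1 if connectivity == 6 else 3)


def remove_fragments(mask: LabelMask, cfg: PostprocessConfig | None = None) -> LabelMask:
    """Per label, keep the largest component or all components >= min_size.

    Ties in keep_largest mode are broken toward the component containing the
    lowest voxel index (components are labelled in scan order).  Voxel count
    never increases.
    """
    cfg = cfg or PostprocessConfig()
    data = mask.data
    if not data.any():
        warnings.warn("remove_fragments: empty mask returned unchanged")
        return mask.with_data(data.copy())
    out = np.zeros_like(data)
    structure = _structure(cfg.connectivity)
    for lab in (int(v) for v in np.unique(data) if v != 0):
        binary = data == lab
        comp, n = ndi.label(binary, structure=structure)
        if n == 0:
            continue
        sizes = ndi.sum_labels(binary, comp, index=np.arange(1, n + 1))
        if cfg.mode == "keep_largest":
            keep = comp == (int(np.argmax(sizes)) + 1)  # argmax -> first = lowest scan index
        else:
            good = np.flatnonzero(sizes >= cfg.min_size) + 1
            keep = np.isin(comp, good)
        out[keep] = lab
    return mask.with_data(out)


def fill_holes(mask: LabelMask) -> LabelMask:
    """Fill interior background cavities per label (6-connected background).

    Background components connected to the volume border are preserved;
    voxel count never decreases.
    """
    data = mask.data
    out = data.copy()
    structure = _structure(6)
    for lab in (int(v) for v in np.unique(data) if v != 0):
        filled = ndi.binary_fill_holes(data == lab, structure=structure)
        out[filled & (out == 0)] = lab
    return mask.with_data(out)


def compute_volume(mask: LabelMask, label: int | None = None) -> float:
    """Region volume in mm^3: voxel count times voxel volume."""
    count = int(mask.binary(label).sum())
    sx, sy, sz = mask.spacing
    return count * sx * sy * sz


def apply_brain_mask(image: Volume, brain_mask: LabelMask) -> Volume:
    """Zero every voxel outside the mask (the skull-stripped image)."""
    if image.shape != brain_mask.shape:
        raise ValueError(f"geometry mismatch: {image.shape} vs {brain_mask.shape}")
    return image.with_data(np.where(brain_mask.binary(), image.data, 0).astype(image.data.dtype))


def postprocess_mask(mask: LabelMask, cfg: PostprocessConfig | None = None) -> LabelMask:
    """Fragment removal followed (optionally) by hole filling."""
    cfg = cfg or PostprocessConfig()
    out = remove_fragments(mask, cfg)
    if cfg.fill_holes:
        out = fill_holes(out)
    return out
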
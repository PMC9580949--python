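"""Core volumetric containers and NIfTI-1 I/O.

Every stage of the pipeline passes data around as :class:`Volume` (scalar MRI
intensities) or :class:`LabelMask` (integer region labels aligned to a
Volume).  The geometry convention is deliberately simple: axes are ordered
(x, y, z), voxel indices are 0-based, and a voxel at index (i, j, k) sits at
physical point ``origin + (i*sx, j*sy, k*sz)`` in mm.  Files whose headers
carry a non-trivial orientation are reordered to the closest-to-identity
orientation on read so that downstream geometry is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["Volume", "LabelMask", "read_nifti", "write_nifti"]


def _check_geometry(data: np.ndarray, spacing) -> tuple[float, float, float]:
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D data")
    if any(s < 1 for s in data.shape):
        raise ValueError(f"every grid dimension must be >= 1, got {data.shape}")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive mm values, got {spacing}")
    return spacing


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing (mm) and origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = _check_geometry(self.data, self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(data, self.spacing, self.origin)

    def index_to_physical(self, idx) -> np.ndarray:
        """Map (possibly fractional) voxel indices to mm coordinates."""
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)


@dataclass
class LabelMask:
    """A 3D integer label image; 0 is background, 1..K are named regions."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("label mask data must be integer-valued")
            self.data = np.round(self.data).astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("label values must be non-negative")
        self.spacing = _check_geometry(self.data, self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        present = set(int(v) for v in np.unique(self.data)) - {0}
        if not self.labels:
            self.labels = {v: f"label_{v}" for v in sorted(present)}
        else:
            missing = present - set(self.labels)
            if missing:
                raise ValueError(f"values {sorted(missing)} present in data but absent from label table")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, labels: dict[int, str] | None = None) -> "LabelMask":
        return LabelMask(data, self.spacing, self.origin, labels=dict(labels or self.labels))

    def binary(self, label: int | None = None) -> np.ndarray:
        """Boolean foreground view (a single label, or any nonzero label)."""
        if label is None:
            return self.data > 0
        return self.data == label

    def index_to_physical(self, idx) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)


def read_nifti(path, as_mask: bool = False, labels: dict[int, str] | None = None):
    """Read a single-frame 3D NIfTI file as a :class:`Volume` or :class:`LabelMask`.

    The image is reoriented to the canonical closest-to-identity axis order;
    spacing is taken from the header zooms, origin from the affine translation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    if len(img.shape) == 4 and img.shape[3] == 1:
        img = img.slicer[:, :, :, 0]
    if len(img.shape) != 3:
        raise ValueError(f"expected 3D volume, got shape {img.shape} in {path}")
    img = nib.as_closest_canonical(img)
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"non-positive voxel spacing {zooms} in header of {path}")
    data = np.asanyarray(img.dataobj)
    origin = tuple(float(v) for v in img.affine[:3, 3])
    if as_mask:
        return LabelMask(np.round(data).astype(np.int32), zooms, origin, labels=dict(labels or {}))
    return Volume(np.asarray(data, dtype=np.float32), zooms, origin)


def write_nifti(vol, path) -> None:
    """Write a Volume (float32) or LabelMask (unsigned int) as NIfTI-1."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    if isinstance(vol, LabelMask):
        maxval = int(vol.data.max()) if vol.data.size else 0
        dtype = np.uint8 if maxval <= np.iinfo(np.uint8).max else np.uint16
        data = vol.data.astype(dtype)
    else:
        data = vol.data.astype(np.float32)
    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vol.spacing
    affine[:3, 3] = vol.origin
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
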
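"""Paired 3D image/mask data augmentation.

The operator set covers the standard families used to enlarge small
annotated MRI cohorts: flips, voxel dropout, piecewise-affine and elastic
warps, additive Gaussian noise, Gaussian blur, global affine (in-plane
rotation + isotropic scale + translation), rotation about the y axis, and
CLAHE contrast enhancement.  Exactly one operator is applied per augmented
sample (transforms are never chained), with parameters drawn uniformly from
their declared ranges.

Contracts: GEOMETRIC operators apply the identical spatial map to image
(linear interpolation) and mask (nearest-neighbour); PHOTOMETRIC operators
return the mask bit-identical.  Everything is deterministic given the rng.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from skimage import exposure

from .volumes import LabelMask, Volume, read_nifti, write_nifti

__all__ = [
    "AugmentationPolicy",
    "GEOMETRIC_OPERATORS",
    "PHOTOMETRIC_OPERATORS",
    "apply_operator",
    "sample_augmentation",
    "expand_dataset",
]

# operator -> {param: (low, high)}; empty dict = parameter-free
DEFAULT_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "horizontal_flip": {},
    "vertical_flip": {},
    "dropout": {"p": (0.01, 0.05)},
    "piecewise_affine": {"scale": (0.01, 0.07)},
    "elastic": {"alpha": (2.5, 50.0), "sigma": (1.0, 11.0)},
    "additive_gaussian_noise": {"scale": (0.0, 12.75)},
    "gaussian_blur": {"sigma": (0.8, 1.5)},
    "affine": {"rot_z_deg": (-20.0, 20.0), "scale": (0.8, 1.3), "translation_frac": (-0.05, 0.05)},
    "rotate_y": {"angle_deg": (-20.0, 20.0)},
    "clahe": {},
}

GEOMETRIC_OPERATORS = frozenset(
    {"horizontal_flip", "vertical_flip", "piecewise_affine", "elastic", "affine", "rotate_y"}
)
PHOTOMETRIC_OPERATORS = frozenset({"dropout", "additive_gaussian_noise", "gaussian_blur", "clahe"})


@dataclass
class AugmentationPolicy:
    """Operator set with parameter ranges and the single-transform rule.

    ``translation_is_fraction_of_extent`` selects between reading the
    affine translation range as a fraction of the image extent per axis
    (default) or as literal percent values (which at +-0.05% would be
    sub-voxel and effectively inert).
    """

    operators: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_RANGES.items()}
    )
    combine_transforms: bool = False  # fixed: one operator per augmented sample
    translation_is_fraction_of_extent: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.combine_transforms:
            raise ValueError("combining transforms is not supported: one operator per sample")
        unknown = set(self.operators) - set(DEFAULT_RANGES)
        if unknown:
            raise ValueError(f"unknown operators: {sorted(unknown)}")
        if not self.operators:
            raise ValueError("policy must contain at least one operator")


def sample_augmentation(policy: AugmentationPolicy, rng: np.random.Generator) -> tuple[str, dict[str, float]]:
    """Uniformly pick an operator, then draw each parameter uniformly in range."""
    names = sorted(policy.operators)
    name = names[int(rng.integers(len(names)))]
    params = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in sorted(policy.operators[name].items())}
    return name, params


def _check_params(name: str, params: dict, policy: AugmentationPolicy | None) -> None:
    ranges = (policy.operators if policy else DEFAULT_RANGES).get(name)
    if ranges is None:
        raise ValueError(f"unknown operator {name!r}")
    for k, v in params.items():
        if k not in ranges:
            raise ValueError(f"unknown parameter {k!r} for operator {name!r}")
        lo, hi = ranges[k]
        if not (lo <= v <= hi):
            raise ValueError(f"{name}.{k}={v} outside range [{lo}, {hi}]")


def _warp(image: np.ndarray, mask: np.ndarray | None, coords) -> tuple[np.ndarray, np.ndarray | None]:
    out_img = ndi.map_coordinates(image.astype(np.float32), coords, order=1, mode="constant", cval=0.0)
    out_msk = None
    if mask is not None:
        out_msk = ndi.map_coordinates(mask, coords, order=0, mode="constant", cval=0)
    return out_img, out_msk


def _identity_grid(shape):
    return np.meshgrid(*(np.arange(n, dtype=np.float32) for n in shape), indexing="ij")


def _elastic_coords(shape, alpha: float, sigma: float, rng) -> list[np.ndarray]:
    grid = _identity_grid(shape)
    coords = []
    for ax in range(3):
        noise = rng.uniform(-1.0, 1.0, size=shape)
        disp = ndi.gaussian_filter(noise, sigma, mode="reflect") * alpha
        coords.append(grid[ax] + disp.astype(np.float32))
    return coords


def _piecewise_affine_coords(shape, scale: float, rng) -> list[np.ndarray]:
    """Random displacements on a coarse 5x5x4 control grid, smoothly
    interpolated to a dense field.

    Node displacement std = scale * local cell size, so the warp is a jitter
    of locally-affine patches: neighbouring cells deform almost rigidly and
    total mask volume stays nearly preserved even at the top of the scale
    range."""
    nodes = (5, 5, 4)
    grid = _identity_grid(shape)
    coords = []
    for ax in range(3):
        # std = half the local cell size at the top of the scale range keeps
        # the warp locally affine and object volumes nearly preserved
        cell = shape[ax] / (nodes[ax] - 1)
        disp_nodes = rng.normal(0.0, 0.5 * scale * cell, size=nodes)
        zoom = [s / n for s, n in zip(shape, nodes)]
        disp = ndi.zoom(disp_nodes, zoom, order=3, mode="nearest", grid_mode=True)
        disp = disp[: shape[0], : shape[1], : shape[2]]
        coords.append(grid[ax] + disp.astype(np.float32))
    return coords


def _apply_affine(image, mask, matrix, translation_vox):
    """Forward map y = M(x - c) + c + t about the image centre c (voxel units).

    scipy resamples with output[j] = input[A @ j + offset], so we pass the
    pull-back A = M^-1, offset = c - M^-1 (c + t).
    """
    inv = np.linalg.inv(matrix)
    center = (np.asarray(image.shape, dtype=float) - 1) / 2.0
    offset = center - inv @ (center + translation_vox)
    out_img = ndi.affine_transform(image.astype(np.float32), inv, offset=offset, order=1, mode="constant", cval=0.0)
    out_msk = None
    if mask is not None:
        out_msk = ndi.affine_transform(mask, inv, offset=offset, order=0, mode="constant", cval=0)
    return out_img, out_msk


def _clahe(image: np.ndarray) -> np.ndarray:
    """Slice-by-slice CLAHE along z, 8x8 tiles, clip limit 0.01."""
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        return image.astype(np.float32)
    scaled = (image - lo) / (hi - lo)
    out = np.empty_like(scaled, dtype=np.float64)
    kernel = (max(image.shape[0] // 8, 1), max(image.shape[1] // 8, 1))
    for k in range(image.shape[2]):
        out[:, :, k] = exposure.equalize_adapthist(scaled[:, :, k], kernel_size=kernel, clip_limit=0.01)
    return (out * (hi - lo) + lo).astype(np.float32)


def apply_operator(
    image: Volume,
    mask: LabelMask | None,
    name: str,
    params: dict[str, float],
    rng: np.random.Generator,
    policy: AugmentationPolicy | None = None,
) -> tuple[Volume, LabelMask | None]:
    """Apply one named operator to an aligned image/mask pair."""
    if mask is not None and image.shape != mask.shape:
        raise ValueError(f"image/mask shape mismatch: {image.shape} vs {mask.shape}")
    _check_params(name, params, policy)
    img = image.data
    msk = mask.data if mask is not None else None
    out_msk = msk  # photometric default: untouched

    if name == "horizontal_flip":
        out_img = img[::-1, :, :].copy()
        out_msk = msk[::-1, :, :].copy() if msk is not None else None
    elif name == "vertical_flip":
        out_img = img[:, ::-1, :].copy()
        out_msk = msk[:, ::-1, :].copy() if msk is not None else None
    elif name == "dropout":
        keep = rng.random(img.shape) >= params["p"]
        out_img = np.where(keep, img, 0).astype(np.float32)
    elif name == "piecewise_affine":
        coords = _piecewise_affine_coords(img.shape, params["scale"], rng)
        out_img, out_msk = _warp(img, msk, coords)
    elif name == "elastic":
        coords = _elastic_coords(img.shape, params["alpha"], params["sigma"], rng)
        out_img, out_msk = _warp(img, msk, coords)
    elif name == "additive_gaussian_noise":
        # scale is on an 8-bit-equivalent intensity axis: rescale to [0,255], add, rescale back
        lo, hi = float(img.min()), float(img.max())
        span = hi - lo if hi > lo else 1.0
        v255 = (img - lo) / span * 255.0
        v255 = v255 + rng.normal(0.0, max(params["scale"], 1e-12), size=img.shape)
        out_img = (v255 / 255.0 * span + lo).astype(np.float32)
    elif name == "gaussian_blur":
        out_img = ndi.gaussian_filter(img.astype(np.float32), params["sigma"], mode="reflect")
    elif name == "affine":
        theta = np.deg2rad(params["rot_z_deg"])
        s = params["scale"]
        c, sn = np.cos(theta), np.sin(theta)
        matrix = np.array([[c * s, -sn * s, 0.0], [sn * s, c * s, 0.0], [0.0, 0.0, s]])
        frac = params["translation_frac"]
        pol = policy or AugmentationPolicy()
        if pol.translation_is_fraction_of_extent:
            translation = frac * np.asarray(img.shape, dtype=float)
        else:  # literal percent reading: frac is already in percent units
            translation = frac / 100.0 * np.asarray(img.shape, dtype=float)
        out_img, out_msk = _apply_affine(img, msk, matrix, translation)
    elif name == "rotate_y":
        theta = np.deg2rad(params["angle_deg"])
        c, sn = np.cos(theta), np.sin(theta)
        matrix = np.array([[c, 0.0, sn], [0.0, 1.0, 0.0], [-sn, 0.0, c]])
        out_img, out_msk = _apply_affine(img, msk, matrix, np.zeros(3))
    elif name == "clahe":
        out_img = _clahe(img)
    else:  # pragma: no cover - guarded by _check_params
        raise ValueError(f"unknown operator {name!r}")

    out_volume = image.with_data(np.asarray(out_img, dtype=np.float32))
    out_mask = mask.with_data(out_msk) if mask is not None else None
    return out_volume, out_mask


def augment_pair(
    image: Volume, mask: LabelMask | None, policy: AugmentationPolicy, rng: np.random.Generator
) -> tuple[Volume, LabelMask | None, str, dict[str, float]]:
    """Sample one operator from the policy and apply it."""
    name, params = sample_augmentation(policy, rng)
    out_img, out_msk = apply_operator(image, mask, name, params, rng, policy=policy)
    return out_img, out_msk, name, params


def expand_dataset(
    staged_dir,
    output_dir,
    policy: AugmentationPolicy | None = None,
    copies_per_sample: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Write originals plus ``copies_per_sample`` augmented pairs per original.

    The augmented-sample count is explicit: n originals yield
    ``n * (1 + copies_per_sample)`` pairs.  Per-sample provenance (operator,
    parameters, seed) is logged to ``augmentation_log.csv``; equal seeds give
    bit-identical outputs.
    """
    if copies_per_sample < 0:
        raise ValueError("copies_per_sample must be >= 0")
    policy = policy or AugmentationPolicy(seed=seed)
    staged_dir, output_dir = Path(staged_dir), Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    images = sorted(staged_dir.glob("img_*.nii*"))
    if not images:
        raise FileNotFoundError(f"no img_* files in {staged_dir}")
    children = np.random.SeedSequence(seed).spawn(len(images))
    rows = []
    for idx, img_path in enumerate(images):
        msk_path = img_path.with_name(img_path.name.replace("img_", "msk_"))
        image = read_nifti(img_path)
        mask = read_nifti(msk_path, as_mask=True) if msk_path.exists() else None
        stem = img_path.name.split(".")[0]
        write_nifti(image, output_dir / img_path.name)
        if mask is not None:
            write_nifti(mask, output_dir / msk_path.name)
        rows.append({"source": img_path.name, "output": img_path.name, "operator": "original", "params": "{}", "seed": ""})
        child_seeds = children[idx].generate_state(max(copies_per_sample, 1)) % (2**31 - 1)
        for c in range(copies_per_sample):
            sub_seed = int(child_seeds[c])
            rng = np.random.default_rng(sub_seed)
            aug_img, aug_msk, name, params = augment_pair(image, mask, policy, rng)
            out_img_name = f"{stem}_aug{c:02d}.nii.gz"
            write_nifti(aug_img, output_dir / out_img_name)
            if aug_msk is not None:
                out_msk_name = out_img_name.replace("img_", "msk_")
                write_nifti(aug_msk, output_dir / out_msk_name)
            rows.append(
                {
                    "source": img_path.name,
                    "output": out_img_name,
                    "operator": name,
                    "params": repr({k: round(v, 6) for k, v in params.items()}),
                    "seed": sub_seed,
                }
            )
    log = pd.DataFrame(rows)
    log.to_csv(output_dir / "augmentation_log.csv", index=False)
    return log
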
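"""Synthetic mouse-head MRI phantoms with known ground truth.

A phantom is an ellipsoidal "brain" of bright tissue surrounded by a darker
skull shell and background, with a small bright sphere attached at the brain
surface standing in for a small cerebellar lobule (the paraflocculus).  A
smooth multiplicative bias field emulates receive-coil shading and additive
Gaussian noise emulates acquisition noise.  Two constructors mirror the two
acquisition regimes seen in practice: in-vivo scans (anisotropic voxels,
lower contrast, more noise) and ex-vivo scans (isotropic voxels, higher
contrast, less noise).

Nothing here attempts real neuroanatomy or MR physics; the purpose is a
fully controlled test bed where every mask is exact by construction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .volumes import LabelMask, Volume, write_nifti

__all__ = ["PhantomSpec", "in_vivo_like", "ex_vivo_like", "generate_phantom", "generate_cohort"]

LABEL_NAMES = {1: "brain", 2: "paraflocculus"}


@dataclass
class PhantomSpec:
    """Geometry and intensity parameters of one synthetic head.

    Lengths are mm.  ``tissue_means`` orders background < skull < brain so
    the contrast ordering of T2w head MRI is preserved; the lobule is given
    a slightly brighter mean so direct small-region segmentation is learnable.
    """

    shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (0.18, 0.18, 0.42)
    brain_semi_axes: tuple[float, float, float] = (3.6, 2.9, 2.6)
    skull_thickness: float = 0.5
    lobule_radius: float = 0.8
    lobule_offset: tuple[float, float, float] = (0.75, 0.55, -0.30)
    tissue_means: tuple[float, float, float, float] = (10.0, 60.0, 140.0, 170.0)
    noise_sigma: float = 6.0
    bias_amplitude: float = 0.15
    seed: int = 0

    def center_mm(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) * np.asarray(self.spacing) / 2.0

    def validate(self) -> None:
        shape = np.asarray(self.shape)
        spacing = np.asarray(self.spacing)
        semi = np.asarray(self.brain_semi_axes)
        if np.any(shape < 1) or np.any(spacing <= 0) or np.any(semi <= 0):
            raise ValueError("shape, spacing and brain semi-axes must be positive")
        if not (0 <= self.bias_amplitude < 1):
            raise ValueError("bias_amplitude must lie in [0, 1)")
        extent = (shape - 1) * spacing
        outer = semi + self.skull_thickness + abs(self.lobule_radius)
        if np.any(2 * outer >= extent):
            raise ValueError(
                f"phantom geometry (outer semi-axes {outer} mm) does not fit the "
                f"grid extent {extent} mm without clipping"
            )


def in_vivo_like(**overrides) -> PhantomSpec:
    """Anisotropic (z ~ 8x in-plane), lower contrast, noisier regime."""
    spec = PhantomSpec(
        shape=(80, 80, 14),
        spacing=(0.13, 0.13, 1.04),
        tissue_means=(10.0, 55.0, 120.0, 145.0),
        noise_sigma=9.0,
        bias_amplitude=0.2,
    )
    return dataclasses.replace(spec, **overrides)


def ex_vivo_like(**overrides) -> PhantomSpec:
    """Isotropic, high-contrast, low-noise regime."""
    spec = PhantomSpec(
        shape=(72, 72, 72),
        spacing=(0.16, 0.16, 0.16),
        tissue_means=(8.0, 55.0, 160.0, 195.0),
        noise_sigma=3.0,
        bias_amplitude=0.1,
    )
    return dataclasses.replace(spec, **overrides)


def _physical_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid(grids, center, semi_axes) -> np.ndarray:
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return q <= 1.0


def _bias_field(shape, amplitude, rng) -> np.ndarray:
    """1 + amplitude * (random second-order polynomial normalized to max |.| = 1)."""
    if amplitude == 0:
        return np.ones(shape, dtype=np.float32)
    coords = [np.linspace(-1.0, 1.0, n) for n in shape]
    x, y, z = np.meshgrid(*coords, indexing="ij")
    terms = [x, y, z, x * y, x * z, y * z, x**2, y**2, z**2]
    coef = rng.uniform(-1.0, 1.0, size=len(terms))
    poly = sum(c * t for c, t in zip(coef, terms))
    poly /= max(np.abs(poly).max(), 1e-12)
    return (1.0 + amplitude * poly).astype(np.float32)


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, LabelMask]:
    """Render one phantom; deterministic for a fixed ``spec.seed``.

    The returned mask has label 1 on brain tissue and label 2 on the lobule;
    the whole-brain region is the union of the two (``mask.data >= 1``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    grids = _physical_grids(spec.shape, spec.spacing)
    center = spec.center_mm()

    semi = np.asarray(spec.brain_semi_axes)
    brain = _ellipsoid(grids, center, semi)
    skull = _ellipsoid(grids, center, semi + spec.skull_thickness) & ~brain

    mask = np.zeros(spec.shape, dtype=np.int32)
    mask[brain] = 1
    if spec.lobule_radius > 0:
        # sphere centred on the brain surface along the (normalized) offset direction
        direction = np.asarray(spec.lobule_offset, dtype=float)
        direction /= max(np.linalg.norm(direction), 1e-12)
        lobule_center = center + direction * semi
        lobule = _ellipsoid(grids, lobule_center, np.full(3, spec.lobule_radius))
        mask[lobule] = 2
        skull = skull & ~(mask > 0)

    bg_mean, skull_mean, brain_mean, lobule_mean = spec.tissue_means
    image = np.full(spec.shape, bg_mean, dtype=np.float32)
    image[skull] = skull_mean
    image[mask == 1] = brain_mean
    image[mask == 2] = lobule_mean

    image *= _bias_field(spec.shape, spec.bias_amplitude, rng)
    if spec.noise_sigma > 0:
        image += rng.normal(0.0, spec.noise_sigma, size=spec.shape).astype(np.float32)

    vol = Volume(image.astype(np.float32), spec.spacing)
    return vol, LabelMask(mask, spec.spacing, labels=dict(LABEL_NAMES))


_JITTERED_SCALARS = ("skull_thickness", "lobule_radius", "noise_sigma", "bias_amplitude")
_JITTERED_TRIPLES = ("brain_semi_axes", "tissue_means")


def _jitter_spec(spec: PhantomSpec, jitter: float, rng: np.random.Generator, seed: int) -> PhantomSpec:
    if not (0.0 <= jitter <= 0.5):
        raise ValueError("jitter fraction must lie in [0, 0.5]")
    changes: dict = {"seed": seed}
    if jitter > 0:
        for name in _JITTERED_SCALARS:
            changes[name] = getattr(spec, name) * (1.0 + rng.uniform(-jitter, jitter))
        for name in _JITTERED_TRIPLES:
            vals = np.asarray(getattr(spec, name), dtype=float)
            changes[name] = tuple(vals * (1.0 + rng.uniform(-jitter, jitter, size=vals.shape)))
    return dataclasses.replace(spec, **changes)


def generate_cohort(
    n: int,
    spec: PhantomSpec | None = None,
    jitter: float = 0.1,
    seed: int = 0,
    out_dir: str | Path = ".",
) -> pd.DataFrame:
    """Write ``n`` image/mask NIfTI pairs plus a manifest CSV.

    Per-sample geometry and intensity parameters are drawn from ``spec``
    with +-``jitter`` relative variation; noise realizations always differ
    between samples.  Two runs with equal seeds produce identical files.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = spec or PhantomSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        sample_seed = int(rng.integers(0, 2**31 - 1))
        sspec = _jitter_spec(spec, jitter, rng, sample_seed)
        vol, mask = generate_phantom(sspec)
        img_path = out_dir / f"img_{i:03d}.nii.gz"
        msk_path = out_dir / f"msk_{i:03d}.nii.gz"
        write_nifti(vol, img_path)
        write_nifti(mask, msk_path)
        row = {"sample": i, "image": img_path.name, "mask": msk_path.name}
        for f in dataclasses.fields(sspec):
            v = getattr(sspec, f.name)
            row[f.name] = str(tuple(v)) if isinstance(v, tuple) else v
        rows.append(row)
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
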
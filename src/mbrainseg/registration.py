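"""Template registration and label propagation.

A subject (moving) volume is aligned to a template (fixed) volume by a
multi-resolution rigid stage followed by an affine stage, maximizing a
similarity metric (normalized cross-correlation by default, joint-histogram
mutual information optionally) with regular-step gradient ascent driven by
finite-difference gradients.  Template region labels are then carried onto
the subject grid through the inverse transform with nearest-neighbour
interpolation — registration-as-segmentation.

Transform convention: an :class:`AffineTransform` maps physical points (mm)
of the FIXED image's space into the MOVING image's space,

    y = M (x - c) + c + t

with rotation centre ``c`` at the fixed image's physical centre.  This is
the resampling ("pull-back") convention: ``apply_transform(moving, T,
fixed)`` directly produces the registered moving image on the fixed grid,
and label propagation onto the subject grid uses ``invert(T)``.

A deformable (SyN-style) refinement is not implemented natively; when
SimpleITK is importable, :func:`deformable_refine` exposes it as an optional
external backend behind the same resampling interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .metrics import cross_correlation
from .volumes import LabelMask, Volume

__all__ = [
    "AffineTransform",
    "RegistrationParams",
    "register",
    "register_rigid_affine",
    "apply_transform",
    "invert",
    "compose",
    "propagate_labels",
    "patch_similarity_qc",
    "deformable_refine",
]


@dataclass
class AffineTransform:
    """3D linear map + translation in physical mm coordinates."""

    matrix: np.ndarray
    translation: np.ndarray
    center: np.ndarray
    kind: str = "affine"  # "rigid" | "affine"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.matrix)) or not np.all(np.isfinite(self.translation)):
            raise ValueError("transform parameters must be finite")
        if self.kind == "rigid":
            should_be_eye = self.matrix @ self.matrix.T
            if not np.allclose(should_be_eye, np.eye(3), atol=1e-5) or not np.isclose(
                np.linalg.det(self.matrix), 1.0, atol=1e-5
            ):
                raise ValueError("rigid transform requires an orthonormal matrix with det +1")

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0), kind="rigid") -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3), np.asarray(center, dtype=float), kind)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return (points - self.center) @ self.matrix.T + self.center + self.translation

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "matrix": self.matrix.tolist(),
                    "translation": self.translation.tolist(),
                    "center": self.center.tolist(),
                    "kind": self.kind,
                },
                indent=2,
            )
        )

    @classmethod
    def from_json(cls, path) -> "AffineTransform":
        d = json.loads(Path(path).read_text())
        return cls(np.asarray(d["matrix"]), np.asarray(d["translation"]), np.asarray(d["center"]), d["kind"])


def invert(T: AffineTransform) -> AffineTransform:
    """Exact algebraic inverse respecting the centre convention."""
    if abs(np.linalg.det(T.matrix)) < 1e-12:
        raise ValueError("singular linear part cannot be inverted")
    inv = np.linalg.inv(T.matrix)
    return AffineTransform(inv, -inv @ T.translation, T.center.copy(), T.kind)


def compose(A: AffineTransform, B: AffineTransform) -> AffineTransform:
    """Composition ``(A o B)(x) = A(B(x))``, expressed at A's centre."""
    # A(B(x)) = Ma(Mb(x - cb) + cb + tb - ca) + ca + ta
    matrix = A.matrix @ B.matrix
    shift = A.matrix @ (B.center + B.translation - B.matrix @ B.center - A.center) + A.center + A.translation
    # rewrite as M(x - c) + c + t with c = A.center
    translation = shift + matrix @ A.center - A.center
    kind = "rigid" if A.kind == "rigid" and B.kind == "rigid" else "affine"
    return AffineTransform(matrix, translation, A.center.copy(), kind)


@dataclass
class RegistrationParams:
    metric: str = "NCC"  # "NCC" | "MI"
    mi_bins: int = 32
    shrink_factors: tuple[int, ...] = (4, 2, 1)
    smoothing_sigmas: tuple[float, ...] = (4.0, 2.0, 1.0)
    gradient_step: float = 0.1
    max_iterations: int = 100
    min_step: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.metric not in ("NCC", "MI"):
            raise ValueError("metric must be 'NCC' or 'MI'")
        if self.mi_bins not in (32, 64, 128):
            raise ValueError("mi_bins must be one of 32, 64, 128")
        if len(self.shrink_factors) != len(self.smoothing_sigmas):
            raise ValueError("shrink_factors and smoothing_sigmas must have equal length")
        if any(
            a < b for a, b in zip(self.shrink_factors, self.shrink_factors[1:])
        ) or self.shrink_factors[-1] < 1:
            raise ValueError("shrink factors must be non-increasing and >= 1")
        if self.gradient_step <= 0:
            raise ValueError("gradient_step must be positive")


# ---------------------------------------------------------------------------
# resampling


def _index_affine(T: AffineTransform, vol, reference) -> tuple[np.ndarray, np.ndarray]:
    """Index-space (matrix, offset) for scipy: vol_index = A @ ref_index + b."""
    s_ref = np.diag(reference.spacing)
    s_vol_inv = np.diag(1.0 / np.asarray(vol.spacing))
    o_ref = np.asarray(reference.origin)
    o_vol = np.asarray(vol.origin)
    A = s_vol_inv @ T.matrix @ s_ref
    b = s_vol_inv @ (T.matrix @ (o_ref - T.center) + T.center + T.translation - o_vol)
    return A, b


def apply_transform(vol: Volume | LabelMask, T: AffineTransform, reference: Volume | LabelMask):
    """Resample ``vol`` onto ``reference``'s grid through ``T`` (physical mm).

    Linear interpolation for images, nearest-neighbour for masks;
    out-of-field voxels are 0.
    """
    A, b = _index_affine(T, vol, reference)
    if isinstance(vol, LabelMask):
        data = ndi.affine_transform(
            vol.data, A, offset=b, output_shape=reference.shape, order=0, mode="constant", cval=0
        )
        return LabelMask(data, reference.spacing, reference.origin, labels=dict(vol.labels))
    data = ndi.affine_transform(
        vol.data.astype(np.float32), A, offset=b, output_shape=reference.shape, order=1, mode="constant", cval=0.0
    )
    return Volume(data, reference.spacing, reference.origin)


# ---------------------------------------------------------------------------
# similarity metrics


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel().astype(np.float64)
    b = b.ravel().astype(np.float64)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("similarity metric undefined on a constant image")
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int) -> float:
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    pxy = hist / max(hist.sum(), 1.0)
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float((pxy[nz] * np.log(pxy[nz] / (px @ py)[nz])).sum())


def _metric_value(metric: str, bins: int, a: np.ndarray, b: np.ndarray) -> float:
    return _ncc(a, b) if metric == "NCC" else _mutual_information(a, b, bins)


# ---------------------------------------------------------------------------
# parameterization


def _euler_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _params_to_transform(theta: np.ndarray, kind: str, center: np.ndarray) -> AffineTransform:
    if kind == "rigid":
        matrix = _euler_matrix(*theta[:3])
        translation = theta[3:6]
    else:
        matrix = np.eye(3) + theta[:9].reshape(3, 3)
        translation = theta[9:12]
    return AffineTransform(matrix, translation, center, kind)


def _transform_to_params(T: AffineTransform, kind: str) -> np.ndarray:
    if kind == "rigid":
        M = T.matrix
        ry = np.arcsin(np.clip(-M[2, 0], -1.0, 1.0))
        if abs(np.cos(ry)) > 1e-8:
            rx = np.arctan2(M[2, 1], M[2, 2])
            rz = np.arctan2(M[1, 0], M[0, 0])
        else:  # gimbal lock: fold everything into rx
            rx = np.arctan2(-M[1, 2], M[1, 1])
            rz = 0.0
        return np.concatenate([[rx, ry, rz], T.translation])
    return np.concatenate([(T.matrix - np.eye(3)).ravel(), T.translation])


def _shrink(vol: Volume, factor: int, sigma: float) -> Volume:
    data = vol.data.astype(np.float32)
    if sigma > 0:
        data = ndi.gaussian_filter(data, sigma, mode="nearest")
    if factor > 1:
        data = data[::factor, ::factor, ::factor]
        spacing = tuple(s * factor for s in vol.spacing)
    else:
        spacing = vol.spacing
    return Volume(data, spacing, vol.origin)


def register(
    moving: Volume,
    fixed: Volume,
    params: RegistrationParams | None = None,
    init: AffineTransform | None = None,
    kind: str = "rigid",
) -> tuple[AffineTransform, float]:
    """Estimate the ``kind`` transform maximizing similarity of moving to fixed.

    Multi-resolution regular-step gradient ascent: at each pyramid level the
    metric gradient with respect to the (scaled) transform parameters is
    estimated by central differences; steps of length ``gradient_step`` in
    scaled-parameter space are taken along the gradient, the step halving
    whenever the metric fails to improve and terminating below ``min_step``.
    Returns the best transform and the final full-resolution metric value.
    """
    params = params or RegistrationParams()
    if kind not in ("rigid", "affine"):
        raise ValueError("kind must be 'rigid' or 'affine'")
    center = np.asarray(fixed.origin) + (np.asarray(fixed.shape) - 1) * np.asarray(fixed.spacing) / 2.0
    if init is None:
        theta = np.zeros(6 if kind == "rigid" else 12)
    else:
        if kind == "rigid" and init.kind != "rigid":
            raise ValueError("cannot initialize a rigid stage from a non-rigid transform")
        # re-express init about this fixed image's centre: t' = t + (M - I)(c - c0)
        t_new = init.translation + (init.matrix - np.eye(3)) @ (center - init.center)
        theta = _transform_to_params(AffineTransform(init.matrix, t_new, center, init.kind), kind)

    extent = float(np.mean((np.asarray(fixed.shape) - 1) * np.asarray(fixed.spacing)))
    if kind == "rigid":
        scales = np.array([1.0, 1.0, 1.0, extent / 2, extent / 2, extent / 2])
    else:
        scales = np.concatenate([np.ones(9), np.full(3, extent / 2)])

    for level, (factor, sigma) in enumerate(zip(params.shrink_factors, params.smoothing_sigmas)):
        level_iters = max(params.max_iterations // 2**level, 30)
        mov_l = _shrink(moving, factor, sigma)
        fix_l = _shrink(fixed, factor, sigma)
        # Evaluate similarity on a quarter-voxel-shifted sample grid: a
        # grid-aligned transform would otherwise be resampled without
        # interpolation, inflating its metric relative to every neighbouring
        # candidate and stalling the optimizer at its starting point.
        ref_l = Volume(
            fix_l.data,
            fix_l.spacing,
            tuple(o + 0.25 * s for o, s in zip(fix_l.origin, fix_l.spacing)),
        )
        fix_s = apply_transform(fix_l, AffineTransform.identity(center), ref_l).data
        ones_l = Volume(np.ones_like(mov_l.data), mov_l.spacing, mov_l.origin)

        def metric_of(th):
            T = _params_to_transform(th * scales, kind, center)
            warped = apply_transform(mov_l, T, ref_l)
            # restrict to voxels sampled inside the moving field of view:
            # zero-filled out-of-field regions would otherwise penalize
            # large motions and bias the optimum toward smaller transforms
            infield = apply_transform(ones_l, T, ref_l).data > 0.999
            if infield.sum() < 0.05 * infield.size:
                return -np.inf
            return _metric_value(
                params.metric, params.mi_bins, warped.data[infield], fix_s[infield]
            )

        v = theta / scales
        current = metric_of(v)
        step = params.gradient_step
        h = 1e-3
        for _ in range(level_iters):
            grad = np.zeros_like(v)
            for i in range(v.size):
                vp, vm = v.copy(), v.copy()
                vp[i] += h
                vm[i] -= h
                grad[i] = (metric_of(vp) - metric_of(vm)) / (2 * h)
            norm = np.linalg.norm(grad)
            if norm < 1e-12:
                break
            candidate = v + step * grad / norm
            value = metric_of(candidate)
            if value > current + 1e-12:
                v, current = candidate, value
                step = min(step * 1.1, params.gradient_step * 4)
            else:
                step *= 0.5
                if step < params.min_step:
                    break
        theta = v * scales

    T = _params_to_transform(theta, kind, center)
    warped = apply_transform(moving, T, fixed)
    final_metric = _metric_value(params.metric, params.mi_bins, warped.data, fixed.data)
    return T, final_metric


def register_rigid_affine(
    moving: Volume, fixed: Volume, params: RegistrationParams | None = None
) -> tuple[AffineTransform, float]:
    """Successive rigid then affine registration (the rigid result seeds the
    affine stage), as used for template alignment."""
    params = params or RegistrationParams()
    T_rigid, _ = register(moving, fixed, params, kind="rigid")
    T_affine, metric = register(moving, fixed, params, init=T_rigid, kind="affine")
    return T_affine, metric


def propagate_labels(
    template_mask: LabelMask, T_moving_to_fixed: AffineTransform, subject: Volume
) -> LabelMask:
    """Carry template labels onto the subject grid through the inverse transform.

    ``T_moving_to_fixed`` is the transform returned by registering the
    subject (moving) to the template (fixed); its inverse maps subject-space
    points into template space, where the labels live.
    """
    return apply_transform(template_mask, invert(T_moving_to_fixed), subject)


def patch_similarity_qc(
    registered: Volume,
    template: Volume,
    n_patches: int = 50,
    patch_size: int = 16,
    seed: int = 0,
) -> pd.DataFrame:
    """Similarity of random interior patches of a registered volume vs the
    template: per-patch NCC, MI and SSIM plus a summary row is returned as a
    tidy table (registration quality control)."""
    from skimage.metrics import structural_similarity

    if registered.shape != template.shape:
        raise ValueError(f"aligned grids required: {registered.shape} vs {template.shape}")
    shape = np.asarray(registered.shape)
    if np.any(patch_size > shape):
        raise ValueError(f"patch size {patch_size} exceeds grid {tuple(shape)}")
    rng = np.random.default_rng(seed)
    rows = []
    data_range = float(
        max(registered.data.max(), template.data.max()) - min(registered.data.min(), template.data.min())
    )
    for i in range(n_patches):
        lo = np.array([rng.integers(0, s - patch_size + 1) for s in shape])
        sl = tuple(slice(a, a + patch_size) for a in lo)
        a = registered.data[sl]
        b = template.data[sl]
        if a.std() == 0 or b.std() == 0:
            ncc = np.nan
            ssim = np.nan
        else:
            ncc = _ncc(a, b)
            ssim = structural_similarity(a, b, data_range=max(data_range, 1e-12))
        mi = _mutual_information(a, b, 32)
        rows.append({"patch": i, "x": lo[0], "y": lo[1], "z": lo[2], "ncc": ncc, "mi": mi, "ssim": ssim})
    table = pd.DataFrame(rows)
    table.attrs["summary"] = {
        "mean_ncc": float(np.nanmean(table["ncc"])),
        "mean_mi": float(np.nanmean(table["mi"])),
        "mean_ssim": float(np.nanmean(table["ssim"])),
    }
    return table


def deformable_refine(moving: Volume, fixed: Volume, init: AffineTransform | None = None):
    """Optional SyN-style deformable refinement via the SimpleITK backend.

    Returns (warped_moving, displacement_field_mm).  Raises ImportError when
    SimpleITK is not installed; the native pipeline is rigid+affine only.
    """
    import SimpleITK as sitk

    def to_sitk(vol: Volume) -> "sitk.Image":
        img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.T.astype(np.float32)))
        img.SetSpacing(tuple(float(s) for s in vol.spacing))
        img.SetOrigin(tuple(float(o) for o in vol.origin))
        return img

    mov = to_sitk(apply_transform(moving, init, fixed) if init is not None else moving)
    fix = to_sitk(fixed)
    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsCorrelation()
    reg.SetOptimizerAsGradientDescent(learningRate=0.5, numberOfIterations=30)
    tx = sitk.DisplacementFieldTransform(
        sitk.TransformToDisplacementField(
            sitk.Transform(3, sitk.sitkIdentity),
            sitk.sitkVectorFloat64,
            fix.GetSize(),
            fix.GetOrigin(),
            fix.GetSpacing(),
            fix.GetDirection(),
        )
    )
    reg.SetInitialTransform(tx, inPlace=True)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.Execute(fix, mov)
    warped = sitk.Resample(mov, fix, tx, sitk.sitkLinear, 0.0)
    out = Volume(sitk.GetArrayFromImage(warped).T.copy(), fixed.spacing, fixed.origin)
    field = sitk.GetArrayFromImage(tx.GetDisplacementField())
    return out, field
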
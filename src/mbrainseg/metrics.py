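"""Segmentation evaluation: overlap scores, Hausdorff surface distance,
residual volume and whole-volume cross-correlation.

With G the ground-truth voxel set and P the predicted set:

    Dice        = 2|G n P| / (|G| + |P|)
    Jaccard     = |G n P| / |G u P|
    PPV         = |G n P| / |P|
    Sensitivity = |G n P| / |G|
    Hausdorff   = max(h(G,P), h(P,G)),  h(G,P) = max_{g in dG} min_{p in dP} d(g,p)

where d is Euclidean distance in mm (voxel spacing applied) and dG denotes
the boundary voxels of G (set voxels with at least one face neighbour
outside the set).  Residual volume is 100*|vol(P)-vol(G)|/vol(G).

Convention for degenerate inputs: when both sets are empty every overlap
metric is 1.0 (a perfect prediction of absence) and the report carries an
``empty_sets`` flag; when exactly one set is empty the overlaps are 0.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .volumes import LabelMask, Volume

__all__ = [
    "overlap_metrics",
    "hausdorff_distance",
    "residual_volume_pct",
    "cross_correlation",
    "evaluate",
    "SegmentationReport",
]


def _as_bool(mask, label=None) -> np.ndarray:
    if isinstance(mask, LabelMask):
        return mask.binary(label)
    arr = np.asarray(mask)
    if label is None:
        return arr > 0
    return arr == label


def _check_same_geometry(a, b) -> None:
    if tuple(a.shape) != tuple(b.shape):
        raise ValueError(f"geometry mismatch: shapes {a.shape} vs {b.shape}")
    if isinstance(a, (Volume, LabelMask)) and isinstance(b, (Volume, LabelMask)):
        if not np.allclose(a.spacing, b.spacing, atol=1e-9):
            raise ValueError(f"geometry mismatch: spacings {a.spacing} vs {b.spacing}")


def overlap_metrics(G, P, label: int | None = None) -> tuple[float, float, float, float]:
    """Return (dice, jaccard, ppv, sensitivity) for one label (or any-foreground)."""
    _check_same_geometry(G, P)
    g = _as_bool(G, label)
    p = _as_bool(P, label)
    ng, np_, inter = int(g.sum()), int(p.sum()), int((g & p).sum())
    if ng == 0 and np_ == 0:
        return 1.0, 1.0, 1.0, 1.0
    union = ng + np_ - inter
    dice = 2.0 * inter / (ng + np_)
    jaccard = inter / union if union else 0.0
    ppv = inter / np_ if np_ else 0.0
    sens = inter / ng if ng else 0.0
    return dice, jaccard, ppv, sens


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Set voxels having >= 1 face neighbour outside the set (grid edge counts)."""
    import scipy.ndimage as ndi

    eroded = ndi.binary_erosion(mask, structure=ndi.generate_binary_structure(3, 1), border_value=0)
    return np.argwhere(mask & ~eroded)


def hausdorff_distance(G, P, spacing=None, label: int | None = None) -> float:
    """Symmetric boundary Hausdorff distance in mm."""
    if spacing is None:
        if not isinstance(G, (LabelMask, Volume)):
            raise ValueError("spacing required when masks are plain arrays")
        spacing = G.spacing
    _check_same_geometry(G, P)
    g = _as_bool(G, label)
    p = _as_bool(P, label)
    if not g.any() or not p.any():
        raise ValueError("Hausdorff distance undefined for an empty mask")
    sp = np.asarray(spacing, dtype=float)
    bg = _boundary_voxels(g) * sp
    bp = _boundary_voxels(p) * sp
    d_gp = cKDTree(bp).query(bg, k=1)[0].max()
    d_pg = cKDTree(bg).query(bp, k=1)[0].max()
    return float(max(d_gp, d_pg))


def residual_volume_pct(G, P, spacing=None, label: int | None = None) -> float:
    """100 * |vol(P) - vol(G)| / vol(G); spacing cancels so counts suffice."""
    _check_same_geometry(G, P)
    ng = int(_as_bool(G, label).sum())
    np_ = int(_as_bool(P, label).sum())
    if ng == 0:
        raise ValueError("residual volume undefined for empty ground truth")
    return 100.0 * abs(np_ - ng) / ng


def cross_correlation(A, B, mask=None) -> float:
    """Pearson correlation of voxel intensities, optionally within a mask."""
    a = A.data if isinstance(A, Volume) else np.asarray(A)
    b = B.data if isinstance(B, Volume) else np.asarray(B)
    if a.shape != b.shape:
        raise ValueError(f"geometry mismatch: shapes {a.shape} vs {b.shape}")
    if mask is not None:
        sel = _as_bool(mask)
        a, b = a[sel], b[sel]
    a = a.astype(np.float64).ravel()
    b = b.astype(np.float64).ravel()
    if a.std() == 0 or b.std() == 0:
        raise ValueError("cross-correlation undefined for constant input")
    return float(np.corrcoef(a, b)[0, 1])


@dataclass
class SegmentationReport:
    dice: float
    jaccard: float
    ppv: float
    sensitivity: float
    hausdorff_mm: float
    residual_volume_pct: float
    empty_sets: bool = False
    per_label: dict[int, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "dice": self.dice,
            "jaccard": self.jaccard,
            "ppv": self.ppv,
            "sensitivity": self.sensitivity,
            "hausdorff_mm": self.hausdorff_mm,
            "residual_volume_pct": self.residual_volume_pct,
            "empty_sets": self.empty_sets,
        }
        if self.per_label:
            d["per_label"] = self.per_label
        return d


def _single_report(g, p, spacing) -> tuple[float, float, float, float, float, float, bool]:
    dice, jac, ppv, sens = overlap_metrics(g, p)
    empty = not g.any() and not p.any()
    if g.any() and p.any():
        hd = hausdorff_distance(g, p, spacing)
    else:
        hd = 0.0 if empty else float("inf")
    rv = residual_volume_pct(g, p) if g.any() else (0.0 if empty else float("inf"))
    return dice, jac, ppv, sens, hd, rv, empty


def evaluate(G: LabelMask, P: LabelMask, spacing=None) -> SegmentationReport:
    """Full report over any-foreground, plus per-label breakdown when multi-label."""
    _check_same_geometry(G, P)
    spacing = spacing or (G.spacing if isinstance(G, LabelMask) else None)
    if spacing is None:
        raise ValueError("spacing required")
    g_any = _as_bool(G)
    p_any = _as_bool(P)
    dice, jac, ppv, sens, hd, rv, empty = _single_report(g_any, p_any, spacing)
    report = SegmentationReport(dice, jac, ppv, sens, hd, rv, empty_sets=empty)
    g_data = G.data if isinstance(G, LabelMask) else np.asarray(G)
    p_data = P.data if isinstance(P, LabelMask) else np.asarray(P)
    labels = sorted(set(np.unique(g_data)) | set(np.unique(p_data)) - {0})
    labels = [int(v) for v in labels if v != 0]
    if len(labels) > 1:
        for lab in labels:
            d, j, pv, sn, h, r, _ = _single_report(g_data == lab, p_data == lab, spacing)
            report.per_label[lab] = {
                "dice": d, "jaccard": j, "ppv": pv, "sensitivity": sn,
                "hausdorff_mm": h, "residual_volume_pct": r,
            }
    return report
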
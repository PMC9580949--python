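"""Template registration and label propagation on phantoms.

Registers a subject phantom to a geometry-jittered "template" phantom
(rigid then affine), carries the template's region labels back onto the
subject through the inverse transform, and compares propagated region
volumes with the subject's exact ground truth.
"""

import numpy as np

import mbrainseg as mb
from mbrainseg.registration import patch_similarity_qc, propagate_labels, register_rigid_affine

subj_vol, subj_mask = mb.generate_phantom(mb.PhantomSpec(noise_sigma=0.0, bias_amplitude=0.0, seed=8))
tmpl_vol, tmpl_mask = mb.generate_phantom(
    mb.PhantomSpec(
        noise_sigma=0.0, bias_amplitude=0.0, seed=31,
        brain_semi_axes=(3.78, 2.78, 2.68), lobule_radius=0.82, skull_thickness=0.48,
    )
)

T, ncc = register_rigid_affine(subj_vol, tmpl_vol)
print(f"rigid+affine registration NCC: {ncc:.4f} (1.0 = perfect alignment)")

regions = propagate_labels(tmpl_mask, T, subj_vol)
for label, name in [(1, "brain"), (2, "paraflocculus")]:
    gt = mb.compute_volume(subj_mask) if label == 1 else mb.compute_volume(subj_mask, 2)
    got = mb.compute_volume(regions) if label == 1 else mb.compute_volume(regions, 2)
    err = abs(got - gt) / gt * 100
    print(f"{name:14s} true {gt:7.3f} mm^3  propagated {got:7.3f} mm^3  error {err:5.1f}%")
print("the large region lands within a few percent; the tiny lobule does not -")
print("which is why small structures get a dedicated direct segmentation model")

warped = mb.apply_transform(subj_vol, T, tmpl_vol)
qc = patch_similarity_qc(warped, tmpl_vol, n_patches=20, patch_size=16, seed=0)
print("patch QC:", {k: round(v, 3) for k, v in qc.attrs["summary"].items()})
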
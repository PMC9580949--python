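# Methods

`mbrainseg` implements an end-to-end workflow for morphological
quantification of mouse-brain structures from T2-weighted MRI: a
convolutional network strips the skull, the stripped brain is registered to
a labelled template whose region labels are carried back onto the subject,
and region volumes are computed for phenotyping. Small structures that
register poorly (the paraflocculus is the canonical example) are segmented
directly by a dedicated model instead. This note records the models,
parameter choices and numerical decisions, and what the synthetic test bed
does and does not establish.

## Synthetic phantoms

Real acquisitions cannot ship with a library, so every stage is exercised
on parametric head phantoms: an ellipsoidal brain (default semi-axes
3.6 x 2.9 x 2.6 mm) inside a darker skull shell (0.5 mm) and background,
with a small bright sphere (radius 0.8 mm, ~200 voxels) attached to the
brain surface as a stand-in for a small cerebellar lobule. Intensities are
composited from per-tissue means (background 10, skull 60, brain 140,
lobule 170), multiplied by a smooth second-order polynomial bias field
(amplitude 0.15) emulating coil shading, plus additive Gaussian noise
(sigma 6). Two constructors mirror the acquisition regimes seen in
practice: `in_vivo_like()` (anisotropic voxels, z spacing 8x in-plane,
higher noise, lower contrast) and `ex_vivo_like()` (isotropic, low noise,
high contrast). Gaussian rather than Rician noise is used deliberately so
the phantom matches the additive-Gaussian family of the augmentation
policy. Cohorts jitter geometry and intensities by a relative fraction
(default +-10%) with per-sample seeds derived from one root seed, so a
cohort is bit-reproducible.

The phantoms have exact ground truth and realistic contrast ordering, but
no real neuroanatomy, no partial-volume or susceptibility effects, and no
MR sequence physics. Passing the synthetic studies therefore demonstrates
that the machinery is correct and that the training/evaluation loop can
learn an intensity-plus-shape segmentation task at desk scale; it does not
certify segmentation accuracy on real scans.

## Staging

Volumes are resampled to a target spacing (linear for images,
nearest-neighbour for masks; output dims `round(n * s_in / s_out)`), then a
fixed-shape window centred on the intensity centre of mass is cut and
zero-padded, then intensities are Z-scored. The centre of mass is computed
on min-shifted intensities only when negative values are present, so
already-normalized inputs are handled and a uniform positive volume yields
its geometric centre. Z-score statistics use all voxels, including
background; masks pass through the identical geometric operations (sharing
the image's centre of mass) and are never normalized. Resampling precedes
cropping. Window rounding is half-up, which makes the crop/pad operation
idempotent and an exact identity when the window equals the grid.

## Augmentation

One operator per augmented sample, never chained; the operator is drawn
uniformly from the policy, each parameter uniformly from its range:
horizontal/vertical flip; voxel dropout p in (0.01, 0.05); piecewise-affine
warp, scale (0.01, 0.07); elastic warp, alpha (2.5, 50) and sigma (1, 11)
voxels; additive Gaussian noise, scale (0, 12.75) on an 8-bit-equivalent
intensity axis (intensities are mapped to [0, 255], noised, mapped back, so
the operator composes predictably with Z-scored data); Gaussian blur,
sigma (0.8, 1.5) with reflective boundaries (mean-preserving); global
affine with in-plane rotation +-20 deg, isotropic scale (0.8, 1.3) and
translation up to +-5% of the extent per axis; rotation about y +-20 deg;
and slice-wise CLAHE (8x8 tiles, clip limit 0.01). The affine translation
range is exposed as a config switch between "fraction of extent" (default)
and a literal percent reading, which at 0.05% would be sub-voxel and
inert.

Geometric operators apply one spatial map to both members of a pair
(linear interpolation for the image, nearest-neighbour for the mask,
rotation about the image centre, out-of-field zero); photometric operators
return the mask untouched. The elastic field is Gaussian-smoothed uniform
noise scaled by alpha; the piecewise-affine field interpolates normal
displacements from a 5x5x4 control grid with standard deviation half the
local cell size at a given scale — chosen so the warp stays locally affine
and keeps object volumes within the documented 10% band even at the top of
the range. Dataset expansion writes originals plus k augmented copies per
original with per-(sample, copy) seeds spawned from one root seed, so the
count is explicit (n originals -> n(1+k) pairs) and two runs with equal
seeds are bit-identical.

## Network

A residual 3D U-Net operating on whole volumes (no patches or tiling),
batch size 1. Each encoder level applies a channel-setting convolution
(stride 2 from level 1 down, doubling filters) and a pre-activation
residual context block: instance norm -> leaky ReLU (slope 0.01) -> 3x3x3
conv -> dropout -> instance norm -> leaky ReLU -> conv, around an identity
shortcut. The decoder upsamples by nearest-neighbour repeat followed by a
convolution (avoiding checkerboard artifacts), concatenates the matching
encoder features, and reduces filters with a 3x3x3 + 1x1x1 localization
pair; a 1x1x1 head and channel softmax yield per-voxel class
probabilities on the input grid. There is a single output head (no deep
supervision). Input dims must be divisible by 2^(depth-1).

The loss is class-weighted soft Dice,
`1 - sum_c w_c (2 sum p_c t_c + eps) / (sum p_c + sum t_c + eps)` with
eps = 1e-5 and weights normalized to sum to one; the default weights are
inverse class-voxel frequencies over the training set, which counters the
background/foreground imbalance of head MRI (the formula behind the
weighting is a package choice). Training uses Adam, an 80/20
train/validation split, learning rate multiplied by 0.7 after 15 stagnant
validation epochs, early stopping after 3x that patience, and retention of
the best-validation weights. Binary models threshold the foreground
probability at 0.5; multi-class models take the voxel argmax.

The network runs on a small reverse-mode automatic-differentiation engine
written over numpy (convolutions evaluated as shifted-view matmuls against
BLAS; input patches re-materialized during the backward pass to cap peak
memory). Every primitive's derivative is checked against central finite
differences in the test suite, and the convolution forward pass against an
independent `scipy.ndimage` oracle. Hyperparameter selection is exposed as
a plain deterministic grid search ranked by best validation loss.

Reference configurations: the full-scale models use depth 5 (4 for the
isotropic small-region model), 16 base filters (24 for the anisotropic
small-region model), dropout 0.08-0.2, initial learning rate 5e-5 and up
to 500 epochs. The desk-scale configuration exercised throughout the test
suite is depth 3, 8 base filters, 64x64x32 inputs, initial learning rate
1e-3 and 2 epochs — sized so a full training study runs in minutes on one
CPU core while leaving the optimization dynamics (plateau decay, early
stopping, best-weight retention) intact.

## Post-processing

Per label: keep the largest 26-connected component (or all components
above a size threshold; ties break toward the component containing the
lowest voxel index in scan order), then fill interior background cavities
using 6-connected background (cavities open to the volume border are
preserved). Both operations are idempotent. Volumes are voxel count times
voxel volume; skull stripping multiplies the image by the binary mask.

## Registration and label propagation

Rigid (3 Euler angles + translation) then affine (12 parameters seeded by
the rigid result) registration maximizes normalized cross-correlation
(default) or joint-histogram mutual information (32/64/128 bins) over a
shrink/smooth pyramid — desk-scale default (4, 2, 1) with sigmas
(4, 2, 1) voxels; the full-scale schedule (8, 4, 2, 1) / (8, 6, 4, 1) is
accepted via config. The optimizer is regular-step gradient ascent on
scaled parameters (rotations in radians, translations scaled by half the
image extent): central-difference gradients, step length 0.1 along the
normalized gradient, step halved when the metric fails to improve and
termination below 1e-3, with mild re-expansion (x1.1) after accepted
steps and per-level iteration caps halving from 100 at the coarsest level.

Two numerical details matter. First, the similarity is evaluated on a
quarter-voxel-shifted sample grid: a grid-aligned candidate would
otherwise be resampled without interpolation and score an artificially
inflated metric, stalling the optimizer at its starting point. Second, the
metric is restricted to voxels sampled inside the moving field of view;
zero-filled out-of-field regions would otherwise penalize large motions
and bias recovered rotations low (both effects were measured at several
degrees of rotation bias on phantoms before these fixes).

Transforms map physical points of the fixed image's space into the moving
image's space (`y = M(x - c) + c + t`, centre c at the fixed image's
physical centre) — the resampling convention, so applying a transform
resamples the moving image directly onto the fixed grid. Label propagation
maps template labels onto the subject grid through the exact algebraic
inverse, nearest-neighbour. A deformable (SyN-style) refinement is not
implemented natively; `deformable_refine` wraps SimpleITK as an optional
external backend when that package is importable. Global affine alignment
recovers large-region volumes well (the whole-brain propagated volume
lands within a few percent on jittered-template phantoms) but cannot
recover a ~200-voxel lobule whose size differs between subject and
template — the measured propagation error for that label is tens of
percent, which is precisely the motivation for the direct small-region
segmentation branch.

Registration quality control samples random interior patches (default 50
of 16^3) of the registered volume against the template and reports NCC,
mutual information and SSIM per patch.

## Evaluation metrics

Dice, Jaccard, PPV and sensitivity are exact set-cardinality ratios;
Hausdorff distance is the symmetrized boundary maximin in mm (boundary =
set voxels with a face neighbour outside; exact maximin, not a percentile
variant), and residual volume is `100 |vol(P) - vol(G)| / vol(G)` (the
absolute difference; magnitudes only). When both masks are empty all
overlap metrics are defined as 1.0 — a perfect prediction of absence —
and the report is flagged; one-empty cases score 0 with infinite
Hausdorff. Whole-volume cross-correlation is the Pearson coefficient.
All of these are verified against brute-force set-counting and
pairwise-distance oracles in the tests.

## Pipeline and reproducibility

`run_pipeline` executes stage -> predict -> post-process -> skull strip ->
register -> propagate -> quantify -> evaluate (Branch I, whole brain) or
replaces the registration stages with a direct small-region prediction
(Branch II), from a YAML config. Every run writes a JSON manifest listing
each stage's parameters before the stage executes, along with seeds,
software version and completion status (created/running/successful/error);
any failure marks the manifest and halts. Re-running from a manifest with
identical inputs reproduces all per-sample CSV outputs bit-exactly —
every stage after training is deterministic, and training is deterministic
under a fixed seed because the whole stack is plain numpy.

## Known limitations

Phantom realism is deliberately minimal (see above). The native
registration is rigid + affine only, with finite-difference gradients —
adequate at desk scale but slower per iteration than analytic-gradient
implementations at full resolution. Whole-image training at the full-scale
matrix sizes (e.g. 448x448x48) is out of reach for the numpy engine on one
CPU; the architecture accepts those configurations but runs them slowly.
MI-driven optimization is noisier than NCC at small image sizes and is
provided mainly for cross-modality use. The exact residual-block layout of
the reference architecture family admits variants; the one used here is
isolated in a single builder class so it can be swapped.
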
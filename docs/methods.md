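# Methods

This note records the model, the parameter choices and their rationale,
the numerical decisions, and what the synthetic phantoms do and do not
establish.

## Localization model

Per vertebral body (VB), a random-forest regressor maps the block feature
of a 3D patch to the displacement from the patch center to the VB center.
Assumptions: the mapping from local appearance to center offset is
learnable (patches carry enough context to know where they are relative to
the target), and errors of individual votes are roughly unbiased, so that
the density of many votes peaks at the true center.

Votes are aggregated with an isotropic Gaussian kernel of width `h = 1.5`
measured in voxel units of the aggregation grid. A per-vote anisotropic
covariance is, in principle, the right kernel, but it is not estimable
from a single tree prediction; the constant-width kernel with unit weights
is the production approximation, used identically by the exact and fast
paths. We read `h` as voxel units (not mm) because it is specified
alongside voxel-based patch sizes; with anisotropic spacing this makes the
kernel anisotropic in mm, matching the anisotropic uncertainty of votes
cast on such grids.

### IFGT aggregation

The improved fast Gauss transform clusters the votes with farthest-point
(Gonzalez) clustering and expands each cluster's contribution in a
truncated multivariate Taylor series about the cluster center. Numerical
policy:

- The error contract is relative: at every grid voxel whose exact response
  exceeds 1e-6 of the response maximum, the fast value is within
  `ifgt_epsilon` (default 1e-2) of the exact one. The response maximum is
  lower-bounded cheaply by evaluating the exact transform at the cluster
  centers; using a lower bound makes every subsequent budget conservative.
- Per target, clusters whose worst-case contribution falls below the
  absolute error budget are skipped (the far-field cutoff that makes the
  transform O(M + N)).
- Per cluster, the expansion order is chosen from the analytic tail bound
  of the exponential series; when the cluster holds fewer sources than the
  expansion has terms, the cluster is summed directly (exactly) instead —
  the standard auto-selection of IFGT implementations. An explicitly
  configured `ifgt_order` forces the expansion path with no cutoff; that
  mode exists for diagnostics and testing.
- When clustering cannot compress the votes (covering radius above `2h`
  even at the cluster cap), the sources are in the regime where direct
  summation is cheaper than any expansion; the transform then evaluates
  the exact separable form (per-axis exponential tables combined by
  einsum). This keeps the contract trivially and is faster.
- Votes that cannot influence any grid voxel above the budget (outside
  the grid by more than a conservative margin) are culled first.

### Chain prior and decoding

Adjacent-pair offsets `c_{i+1} − c_i` are modeled as Gaussians with the
sample mean and the unbiased sample covariance across training subjects.
Small cohorts give rank-deficient covariances, so diagonal entries are
floored at 1 mm² and eigenvalues clamped at 1e-3 of the floor — the
transition densities stay proper without materially widening them.

Decoding uses the top-50 local maxima (3³ neighborhood, plateaus count,
ties toward the lower flat index) of each response as the candidate set;
observation scores are response values normalized to unit sum over the
candidates (making the decoded chain invariant to rescaling any single
response), transitions are the prior densities, and the joint maximum is
found by Viterbi dynamic programming in the log domain. Candidate-set
decoding is an approximation to full-grid decoding; 50 candidates is far
more than the handful of genuine modes a response exhibits.

### Coarse-to-fine

The coarse step votes over the whole volume downsampled in-plane by 4
(block averaging, to anti-alias the coarse features; the slice axis keeps
its resolution), then decodes the chain. The fine step re-votes at full
resolution inside a box around each coarse center and takes the response
argmax. The refinement box must be smaller than the inter-body spacing —
otherwise the box contains a neighboring, nearly identical body and the
ambiguity the coarse+HMM stage just resolved returns. For the phantoms
(24 mm spacing) the half-width is 12 mm; for clinical use it is
configurable (default 30 mm, suited to lumbar spacing).

## Features

Patches are split into `k = 4` blocks per axis (remainder voxels go to the
last blocks); block means — and, for CT, block variances — come from
integral volumes of the intensity and squared intensity, so one feature
costs exactly k³ box queries regardless of patch size. The mean sub-vector
is L1-normalized; the CT variance sub-vector is L1-normalized separately,
so both halves are invariant to global intensity scaling (whether the
original work normalized the concatenated vector jointly is not
determinable; per-half keeps both halves scale-free). All-zero patches
return the uniform mean vector and zero variances rather than dividing by
zero. Variances are clamped at zero against floating-point cancellation.

## Forests

Regression: 20 trees (10 in the reduced phantom study), depth ≤ 12,
min 5 samples per leaf, √d_f random features per split, bootstrap
resampling; leaves store the mean displacement (used for voting) and the
per-axis displacement variance (diagnostic). Classification: same shape
with Gini splits; leaves store foreground fractions. These sizes are
standard forest practice; all are configurable. Training, sampling and
phantom generation take explicit seeds; identical seeds give identical
outputs.

## Segmentation

The ROI half-extent per VB is learned from the center-aligned training
masks (their per-axis reach, dilated by 25%) rather than fixed in mm, so
it adapts to the structure's size. The spatial prior is the
nearest-neighbor-aligned mask average smoothed with a 2-voxel Gaussian
(Parzen window); 2 voxels absorbs inter-subject shape variation without
washing out the boundary. The prior gate `P_s > 0.1` is implemented as a
hard gate: gated-out voxels are background by construction, not merely
skipped for speed. This is a deliberate semantic choice — with the default
weights a voxel with P_s ≤ 0.1 could still cross the 0.5 threshold if its
appearance likelihood were high (0.4·0.1 + 0.6·1 = 0.64), so the gate is
not a no-op and is documented as part of the model. Fusion weights
α = 0.4, β = 0.6; binarization at L ≥ 0.5 (boundary included) keeps the
largest 26-connected component (6-connectivity available).

Training patches for the classifier are balanced 50/50
foreground/background within the ROI, 8×8×8 voxels, labels taken from the
mask at the patch center; patch centers near the volume border are shifted
inward so patches fit.

## Evaluation metrics

MLD and SD use the population (N) divisor for SD, exactly as the summary
statistics are defined for these studies. Detection at tolerance t counts
the boundary as success. Dice of two empty masks is defined as 100%.
Surfaces are marching-cubes iso-surfaces of the (zero-padded) binary
volumes at level 0.5 in physical coordinates; AAD is the one-directional
mean nearest-vertex distance from the automatic surface to ground truth
(a symmetric average is behind a flag), HSD the symmetric Hausdorff
distance of the vertex sets. The mid-sagittal slice of a VB is the slice
through its (rounded) center along the left-right axis; 2D contours are
iso-lines at 0.5.

## Phantoms

`generate_spine_phantom` builds a chain of bright ellipsoids (default five
bodies, radii (10, 8.5, 11) mm, 24 mm apart along y, jittered per body)
on a 40×128×128 grid at (2, 1.25, 1.25) mm — a reduced sagittal-MR
convention with the slice axis along x. Intensities are foreground 1.0 /
background 0.2 with additive Gaussian noise (SD 0.08); the MR flavor adds
per-body intensity variation (4%) and foreground speckle, the CT flavor a
flat plateau. Cohorts add zero-mean subject-level perturbations of the
mean inter-body offset and a global radius scale, so chain priors and
spatial priors see realistic between-subject variation.

What the phantoms emulate: the repetitive chain of similar bright bodies,
anisotropic voxels, noise, and between-subject geometric variation — the
properties the voting, HMM and prior-fusion machinery are built for. What
they do not emulate: realistic vertebra shape (pedicles, endplates),
surrounding anatomy (discs, cord, ribs), bias fields, or pathology.
Passing the phantom studies therefore demonstrates that the pipeline's
machinery is implemented correctly and recovers known ground truth under
the stated conditions; it does not certify clinical-grade accuracy on real
scans.

## Study sizes

The leave-one-out phantom study runs six subjects with forests of 10
trees, N = N′ = 2000 localization patches and M = 3000 segmentation
patches per volume — sizes chosen so the full study (6 folds × training +
detection + segmentation of 5 bodies) completes in a few minutes on one
CPU while leaving comfortable margins to its accuracy thresholds. The
production defaults (20 trees, N = 15000, N′ = 10000, M = 12000) are used
when models are trained through the CLI.

## Known limitations

- Oriented (non-axis-aligned) volume geometries are rejected rather than
  resampled; DICOM series and 4D data are out of scope.
- The VB set is fixed by the training configuration; the pipeline does
  not identify which vertebrae are in an unknown field of view.
- Candidate-set HMM decoding is exact only with respect to its candidate
  lists; a full-grid mode is available for small grids via a large
  `k_candidates`.
- AAD/HSD use iso-surface vertex sets as distance primitives; different
  surface generators would shift distances at the sub-voxel level.
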
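# Methods

`thalseg` implements a complete thalamic-nuclei segmentation pipeline for
dual-inversion-time T1-weighted MRI: quantitative T1/PD mapping, multi-TI
contrast synthesis, harmonized preprocessing, a coordinate-aware 3D U-Net
trained with a masked Dice loss on sparse labels, connected-component
post-processing, and evaluation metrics. This note records the model, its
assumptions, the numerical choices, and what the built-in synthetic phantoms
do and do not establish.

## Signal model and quantitative mapping

A magnetization-prepared inversion-recovery acquisition with inversion time
TI and repetition time TR is modeled voxelwise as

    I = PD · (1 − 2 e^(−TI/T1) + e^(−TR/T1)),

with proton density PD (arbitrary units) and longitudinal relaxation time T1
(ms). Two acquisitions share TR = 4000 ms and differ only in TI — 1400 ms
(MPRAGE) and 400 ms (FGATIR) — giving two measurements per voxel. The model
deliberately omits flip-angle and readout effects; it is a two-parameter
description of the prepared longitudinal magnetization at readout.

**Polarity.** Scanners store magnitudes. At TI = 400 ms most brain tissue is
still inverted, so the signed FGATIR signal is recovered by negating the
whole magnitude volume (`restore_polarity`). This convention is exact only
in the regime where the FGATIR signal is truly negative and the MPRAGE
signal truly positive — approximately T1 ∈ (600, 2000) ms at these timings,
which covers white matter, cortical/thalamic gray matter and all nucleus
tissue classes. Very short-T1 tissue (fat) and very long-T1 tissue (CSF)
violate the assumption and fit to biased values; a per-voxel sign-selection
variant is deliberately not implemented. Tests and acceptance checks that
claim exact recovery restrict themselves to the valid regime, or bypass the
magnitude step by evaluating the signed model directly.

**Fitting.** `fit_qmaps` is a vectorised per-voxel nonlinear least-squares
solver. PD cancels in the ratio of the two measurements, leaving a scalar
root problem in T1, `I_M·f_F(T1) − I_F·f_M(T1) = 0` (written
multiplicatively so a nulled signal never divides); a 96-node log-spaced
scan over the T1 bounds brackets the root, 52 bisection iterations refine
it, the closed-form least-squares PD given T1 follows, and 8 Gauss–Newton
iterations on the joint 2-parameter problem (analytic Jacobian, closed-form
2×2 normal equations) polish both. T1 is constrained to [200, 5000] ms —
the model admits no bound from first principles, and the interval brackets
physiological values at 3 T with margin while preventing divergence at
low-signal voxels. Voxels with no ratio root in bounds, zero measurements,
non-positive PD, or a solution pinned at a bound are flagged invalid rather
than clamped; downstream synthesis emits 0 there. On noiseless input the
solver recovers (PD, T1) to machine precision; the test suite cross-checks
it against an independent `scipy.optimize.brentq` solve of the ratio
equation.

**Null times and multi-TI synthesis.** The inversion time nulling tissue of
a given T1 has the closed form `TI* = T1 · ln(2 / (1 + e^(−TR/T1)))`
(→ T1·ln 2 as TR → ∞); the test oracle re-derives it by bisection.
`synthesize_multi_ti` evaluates the signed model at fixed TR over a TI grid
and takes magnitudes; the default grid is 400–1400 ms in 20 ms steps (51
images), the range over which intra-thalamic contrast varies meaningfully.

## Preprocessing

Bias fields are estimated per modality by a pluggable estimator —
`poly`, a low-order (quadratic) polynomial fit to log-intensity over the
foreground, self-contained and adequate for smooth synthetic gain; or `n4`,
N4 via SimpleITK for real scans. The polynomial estimator cannot separate
anatomy from gain on structured images; its guarantees are stated (and
tested) on homogeneous phantoms only. Because the two modalities must stay
on one intensity scale, both images are divided by the *same* harmonized
field, the voxelwise geometric mean `B_harm = √(B_M · B_F)`; this preserves
the MPRAGE/FGATIR ratio at every voxel exactly.

White matter is segmented from the corrected MPRAGE by fuzzy C-means on
foreground intensities (3 classes, fuzziness m = 2, tolerance 1e−5, ≤300
iterations, centroids initialised at the 0.25/0.5/0.75 intensity quantiles,
falling back to evenly spaced centroids when a dominant tissue collapses the
quantiles). WM is the hard assignment to the highest centroid — WM is the
brightest tissue on MPRAGE. Both images are divided by the mean corrected
MPRAGE intensity over that mask, making the normalized MPRAGE WM mean
exactly 1. Foreground is defined as voxels above 1% of the 99.9th-percentile
intensity, which keeps air from dominating the clusters.

Center cropping uses low-side offset `(N − n) // 2`; an odd surplus drops
the extra voxel from the high-index side. `pad_back` inverts the crop with
fill 0 for both images and labels. Inference applies center cropping only.

## Network

A 4-level 3D U-Net ("4-level" = 4 pooling stages plus a bottleneck). Encoder
stages: two convolution blocks (3×3×3 kernels, instance normalization,
LeakyReLU with negative slope 0.01) then 2×2×2 max pooling. Decoder stages:
trilinear 2× upsampling, one convolution block, concatenation with the
mirrored encoder features, two convolution blocks. A final 3×3×3 convolution
and channel softmax yield 14-channel voxelwise probabilities (background +
13 nuclei). Channel widths double per level from `base_width` (default 16;
tests and desk-scale runs use 8 — the counts are configuration, not a claim).

**Coordinate channels.** Three channels with value `−1 + 2i/(N−1)` at index
i of an axis of extent N (extent-1 axes yield 0) are concatenated to the
input, spanning [−1, 1] with 0 at the center; for even extents such as 96 no
voxel sits exactly at 0. Coordinates are computed on the post-augmentation
crop. All convolutions use replicate padding: with zero padding, border
voxels would receive the coordinate value 0 — the code for "spatial center"
— creating positional ambiguity; replicate padding copies edge values
instead (verified by the constant-input-stays-constant test).

The network, its layers, and all gradients are implemented directly on
NumPy arrays (channel-first, batch size 1) with hand-derived backward
passes; finite-difference gradient checks in the test suite hold them to
1e−3 relative in float64. Two design details worth noting: max-pool
gradients split equally among tied maxima (a measure-zero event for
continuous inputs), and the trilinear upsampling adjoint is implemented in
closed form and verified by dot-product (⟨Ax, y⟩ = ⟨x, Aᵀy⟩) tests.
Convolution biases feeding instance norm are retained for structural
symmetry although the normalization makes them inert.

## Sparse labels and the masked Dice loss

Label volumes contain class ids 0–13 plus the sentinel 100 marking
unlabeled-within-thalamus voxels. The loss restricts to the labeled voxel
set, one-hot encodes the labels, computes per-class soft Dice
`2Σpq / (Σp + Σq + ε)` with ε = 1e−5, and returns one minus the mean over
all 14 classes. Sentinel voxels contribute exactly nothing — perturbing
probabilities there leaves the loss bitwise unchanged (asserted). A class
absent from the labeled voxels scores Dice 0 under the formula as printed,
contributing maximally to the loss; an `ignore_absent` option averages over
present classes instead but is off by default, favoring fidelity to the
stated formula over convenience.

## Augmentation and training schedules

Augmentation stages, applied image-and-labels jointly (trilinear for
images, nearest-neighbor for labels, so no interpolation-created label
values): left-right flip (p = 0.5), affine with per-axis rotations within
±15°, one isotropic scale in [0.9, 1.1] and per-axis translations within 5
voxels, elastic deformation from a 7³ control grid with displacements
uniform in ±7 voxels interpolated by cubic spline, then center-crop, then
gamma correction with log-γ uniform in [−0.3, 0.3] (image only). The stage
order and the per-axis reading of rotation/translation are package
conventions; each stage disables independently and degenerate
configurations collapse to the exact identity. The flip does not permute
label ids (the 13 labels are not hemisphere-paired in this scheme).

Optimization is Adam (lr 1e−3, weight decay 1e−4 folded into the gradient),
batch size 1, seed 1234 by default. Two schedules: `crossval` multiplies the
learning rate by 0.9 after 5 epochs without validation improvement and stops
early after 15 (≤200 epochs); `full` multiplies by 0.9 every 10 epochs and
runs exactly 200 epochs. Both are fully seeded; identical seeds reproduce
identical loss trajectories. The per-epoch log records epoch, learning rate,
train loss, validation loss.

## Post-processing

Two sequential steps on the hard segmentation, both strict in their size
predicates and both using 6-connectivity (the reassignment rule specifies
6-connected neighbors; component extraction uses the same connectivity for
consistency):

1. *Thalamus-level filtering* — binarize labels 1–13 vs background and erase
   components smaller than 200 voxels (a 200-voxel component survives).
2. *Nucleus-level refinement* — per class, components smaller than 10 voxels
   are reassigned whole to the neighbor-label class with the highest mean
   predicted probability over the component (ties to the lower class index);
   classes are processed in ascending order against the original
   segmentation with edits applied to a copy, single pass. A `per_voxel`
   variant reassigns each island voxel independently.

Component labeling is `scipy.ndimage.label`; the suite verifies it against a
brute-force flood fill on hundreds of random grids.

## Metrics and label unification

Because ground truth is sparse, overlap scores would penalize correct
predictions at unlabeled voxels; the primary metric is therefore the
per-class true positive rate over labeled ground-truth voxels, summarized
per subject as a volume-weighted average with ground-truth voxel counts as
weights (the natural reading of "volume-weighted"). Absent classes are
reported missing, never 0. Test–retest agreement uses Dice; volume stability
uses the coefficient of variation with the sample (n−1) standard deviation.
The 13-nuclei → 7-group unification scheme ships as an editable YAML
(`thalseg/data/grouping7.yaml`); the assignment of nuclei to groups is
annotation-protocol configuration, and the shipped default is a best-effort
anatomical assignment users should adapt.

## Synthetic phantoms

`make_phantom` builds an ellipsoidal homogeneous "head" of white matter with
a gray-matter shell and a CSF ventricle (three intensity modes, so tissue
clustering is exercised), plus a central thalamic ellipsoid partitioned into
13 contiguous nuclei by a seeded farthest-point/nearest-seed (Voronoi)
partition in normalized ellipsoid coordinates — so one seed reproduces one
nucleus layout across jittered geometries. Tissue values (WM 800 ms / PD
0.7, GM 1300 / 0.85, CSF 4000 / 1.0, nuclei spread 900–1500 ms at PD 0.85)
are fixture parameters chosen so multi-TI nulling visibly separates nuclei
and the three tissues order correctly on MPRAGE; they are not claims about
real anatomy. Acquisitions are simulated through the signed signal model, a
smooth multiplicative bias field (exp of a random quadratic, default log
amplitude 0.2), and Rician noise via complex Gaussian perturbation (default
σ = 0.01 in PD units, i.e. ~1% of CSF PD and ~1.4% of WM signal scale); an
additive-Gaussian option exists for analytic tests. Sparsification erodes
each nucleus (6-connected, default radius 1) and marks the stripped
intra-thalamic band with the sentinel.

Default extents are 64³ rather than 96³ so CPU runs stay fast; the 96³ path
is covered by a forward-pass smoke test. Desk-scale learnability runs use
32³ center crops, `base_width` 8, and a few hundred gradient steps: a single
fixed phantom is overfit below masked-Dice loss 0.1 within 200 steps, and a
6-train / 2-held-out split of a jittered family reaches volume-weighted TPR
≥ 0.7 within 300 steps. The held-out runs disable the left-right flip and
elastic stages and use mild affine jitter matching the family's geometric
variability. What these phantoms do **not** emulate: realistic thalamus
shape and population variability, partial-volume mixtures, scanner-specific
readout effects, motion, or inter-site contrast differences — so passing
tests demonstrate correctness of the mechanisms (fitting, loss masking,
coordinate encoding, filtering), not clinical-grade accuracy on real scans.

## Known limitations

- The whole-volume polarity negation biases fits outside the
  T1 ∈ (~600, ~2000) ms regime (fat, CSF).
- The polynomial bias estimator is only trustworthy on near-homogeneous
  foregrounds; use the N4 path for real data.
- The NumPy network trains on CPU at desk scale; it is deliberately small
  and has no GPU path.
- Headline accuracy on real cohorts requires real scans, full 96³ training
  and the full schedule, none of which the synthetic suite reproduces.
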
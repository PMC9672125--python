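# Methods

This note documents the models, conventions, and numerical choices behind
voteseg, and what the synthetic experiments do and do not demonstrate.

## Geometry and data model

All grids use a fixed axis convention: array axis 0 is the patient x
(sagittal) direction, axis 1 is y (coronal), axis 2 is z (axial); an axial
slice is a fixed-z plane. Voxel spacing defaults to 0.19 mm isotropic, the
resolution of dental CBCT acquisitions the toolkit targets. Intensities
are Hounsfield units after the file header's rescale slope/intercept; no
scanner-specific recalibration is applied. A `Volume` is a 3D scalar grid
with spacing; a `BinaryMask` is a boolean grid aligned to its volume.
I/O for NIfTI, NRRD, and DICOM series goes through SimpleITK behind the
`io_preprocess` surface, keeping one axis convention for all three formats.

## Preprocessing

**Gaussian denoising.** A 3D Gaussian filter with σ = 1 voxel (the grid is
isotropic, so voxels and millimetres are proportional) removes
high-frequency noise before contouring. Boundary handling is reflective:
zero-padding would darken the border and bias any threshold-based ground
truth toward shrunken contours there. σ = 0 is a strict identity.

**Metallic dental burden (MDB) screen.** Scans dominated by metal
(implants, braces, crowns) produce artifacts that corrupt both training
and ground truth, so they are screened out before analysis. Two HU
thresholds are fixed: TH1 = 3070 (metal-dense) and TH2 = 2500
(enamel-dense). The screening ratio is the ratio of *voxel counts*

    MDBR = #{v > TH1} / #{v > TH2},

i.e. the fraction of enamel-or-denser voxels that are metal-dense, and a
scan is flagged heavy when MDBR > TH3 = 0.4. The count-ratio reading is a
deliberate interpretation: a literal ratio of the thresholds themselves
would be a constant and could never be compared against a 0.4 cutoff. It
is configurable (`th1`, `th2`, `th3` arguments). A scan with no voxel
above TH2 has MDBR defined as 0 — nothing dense enough to judge, so the
scan is conservatively *not* excluded.

**Flip augmentation.** Horizontal (left–right, x-axis) flips double a
dataset; dental anatomy is approximately bilaterally symmetric, so the
flipped images are plausible patients. Flipping is an involution and
intensity-preserving, hence commutes with the MDB screen.

**Semiautomatic contouring.** Ground truth is built slice by slice: a
polygonal ROI restricts a HU threshold, and holes (pulp chambers fall
below enamel/dentin thresholds) are filled per axial slice in 2D —
matching the slice-by-slice workflow the masks come from, and avoiding 3D
fills bleeding through structures that are only open in-plane.

## Multi-view decomposition

Five input representations feed segmentation models: axial, coronal, and
sagittal 2D stacks; 2.5D slabs whose three channels are axial slices
(i−1, i, i+1); and non-overlapping 3D patches (64×64×128 by default,
64×64 in-plane and 128 along z). Conventions:

- **Slab edges** replicate the nearest existing slice, so channel
  semantics ("previous / current / next") hold without inventing
  intensities.
- **Patch tiling** zero-pads the trailing end of each axis to the next
  patch multiple, cuts disjoint blocks in raster order (z fastest — fixed
  for reproducibility, irrelevant to results), and reassembly crops the
  pad. Overlap-and-average sliding windows are out of scope: the voting
  stage, not window blending, is this toolkit's answer to patch-edge
  error.

Every decomposition is exactly invertible; reassembly is bit-identical
for arbitrary shapes (property-tested over random shapes 1–40 per axis).
This is what lets predictions from different representations be voted in
a single volume frame.

## Reference predictor

The bundled predictor is a compact NumPy U-Net (forward pass, hand-written
backpropagation, Adam) supporting 2D, 2.5D (three input channels), and 3D
inputs: per resolution level two 3^d convolutions (stride 1,
zero-padding) each followed by ReLU; 2^d max pooling (stride 2) between
levels going down; nearest-neighbour upsampling followed by a convolution
("up-convolution") with skip concatenation going up; and a final 1^d
convolution to a dual-class softmax (tooth / non-tooth). Reference
configuration: 4 levels, 32 first-layer features, Adam at lr 1e-4 on
binary cross-entropy, batch 12 (2D/2.5D) or 6 (3D), epoch caps 150/200,
input sizes 512×512×1, 512×512×3, 64×64×128.

Choices worth recording:

- **Callbacks.** Learning rate ×0.95 after any 10 consecutive epochs
  without validation-loss improvement (the window then restarts); early
  stop after 50 stalled epochs. The baseline is the validation loss
  evaluated *before* the first epoch, so a run whose validation loss
  never moves decays the LR exactly at epochs 10, 20, … and stops at
  epoch 50. `PlateauSchedule` implements this and is testable in
  isolation.
- **Binarization** at τ = 0.5 reproduces the two-class softmax argmax; an
  exact tie (p = 0.5) resolves to foreground, a fixed documented
  convention.
- **Input normalisation.** HU are shifted/scaled (default ÷1000) before
  the first convolution; raw thousands-scale inputs would saturate the
  early layers. This is an implementation choice of the bundled
  predictor, exposed on `ModelSpec`.
- **Pooling stride.** Pooling is 2^d windows at stride 2 — the standard
  downsampling U-Net topology implied by the 2^(depth−1) divisibility
  requirement on input sizes.
- **Predictor as interface.** `predict_volume` only needs an object with
  a `spec` and a `forward` method; voting and evaluation accept masks
  from any source. The toolkit is fully usable with externally trained
  models.

Full-size configurations are defaults, not test requirements: tests and
the acceptance script train a depth-2 / 8-feature 2D variant on 32×32
phantom slices (seconds on one CPU). That run demonstrates the
optimisation loop and callbacks, not segmentation quality at clinical
scale.

## Majority voting

`majority_vote(masks, k)` marks a voxel foreground when at least k of n
aligned binary masks do. The stock schemes:

| scheme | voters                      | k |
|--------|-----------------------------|---|
| 2.5Dv  | 2Da, 2Dc, 2Ds               | 2 |
| 3.5Dv3 | (2.5Dv), 2.5Da, 3D          | 2 |
| 3.5Dv4 | 2Da, 2Dc, 2Ds, 3D           | 3 |
| 3.5Dv5 | 2Da, 2Dc, 2Ds, 2.5Da, 3D    | 3 |

3.5Dv3 is evaluated as a *nested* vote — its first ballot is itself the
2.5Dv vote — not flattened to five voters. The two are genuinely
different: with the three 2D models positive and 2.5Da/3D negative, the
flat five-way vote passes (3 of 5) while the nested vote sees only 1 of
its 3 ballots. With four voters, strict majority (k = 3) is required, so
a 2–2 tie is negative; conservative ties suit the false-positive-removal
purpose of voting. Both k and the schemes are configurable (YAML-friendly
`scheme_from_dict`).

Voting operates on binarized masks, not probabilities: the fusion target
is the *decisions* of heterogeneous models, which may not emit calibrated
probabilities at all.

For independent voter errors the voted false-positive rate is the
binomial tail P(X ≥ k), X ~ Binomial(n, p) (`fp_suppression_curve`); at
n = 5, p = 0.01, k = 3 this is ≈ 9.85 × 10⁻⁶. The acceptance suite checks
the empirical voted FP rate of simulated independent voters against this
law within three Monte-Carlo standard errors over > 10⁶ voxels.

## Morphological opening (E&D)

The structuring element is the discrete Euclidean ball: integer offsets
with ‖z‖₂ ≤ r on the voxel lattice (33 voxels at the default r = 2; a
city-block or chessboard ball would be a different set and is available
by constructing a custom footprint). Erosion keeps voxels where the
translated ball fits entirely inside the foreground; voxels outside the
grid count as background, so objects touching the border erode there
(the duality erode(M) = ¬dilate(¬M) therefore holds on the interior and
is tested there). Dilation is the union of balls around foreground
voxels, clipped to the grid. `open_ed` is erosion followed by dilation —
3D morphological opening, applied once after fusion or after a
single-model prediction.

Opening is anti-extensive, idempotent, and increasing, and deletes every
connected component that contains no translate of the ball — in
particular any speckle of radius < 2 — while radius-≥2 structures
survive. Because opening never adds foreground, per-slice TP and FP
counts are non-increasing under it, hence specificity and PPV are
non-decreasing and sensitivity and NPV are non-increasing; the phantom
experiments reproduce exactly these directions.

## Slice-based evaluation

Confusion counts (TP/TN/FP/FN) are computed per slice along a chosen axis
(default axial, the acquisition plane) and six metrics derived per slice:

    Ac  = (TP+TN)/(FP+TP+FN+TN)      DSC = 2TP/(FP+2TP+FN)
    Sn  = TP/(TP+FN)                 Sp  = TN/(TN+FP)
    PPV = TP/(TP+FP)                 NPV = TN/(TN+FN)

Zero-denominator policy:

- **Mandatory rule:** a slice with empty ground truth but any false
  positive has DSC = 0 (the formula gives 0/positive). Slice-averaged
  DSC therefore punishes stray predictions on tooth-free slices — the
  failure mode voting addresses — and sits systematically below
  whole-volume DSC on the same masks.
- A slice where both prediction and ground truth are empty has an
  undefined 0/0 DSC; the aggregate scores it as 1 by default (nothing to
  find, nothing found), with exclusion available
  (`empty_empty_dsc="exclude"`) since either reading of "averaging every
  slice" is defensible.
- Sn is undefined when the slice has no ground-truth positives, Sp/PPV/
  NPV likewise for their denominators; undefined slices are excluded
  from that metric's aggregate.

Aggregation pools slices (per-patient averaging is available by
aggregating per patient first); both mean and median are reported, since
heavy-tailed per-slice distributions make them diverge substantially.

**Cross-validation folds** are patient-level: a seeded random equal (or
nearly equal) partition into n_folds subsets (default 4), each subset
serving as the test set exactly once. Splitting by patient, not by
slice, prevents leakage between neighbouring slices of one scan.

## Statistical tests

- **Normality screen:** Kolmogorov–Smirnov against a normal with
  estimated mean/SD, i.e. the Lilliefors variant (statsmodels), since no
  fixed reference normal exists.
- **Paired Wilcoxon signed-rank** for before/after E&D comparisons:
  zero differences dropped (Wilcoxon's convention), exact p for small
  tie-free samples and tie-corrected normal approximation otherwise
  (scipy). All-zero differences raise a degenerate-data error rather
  than returning p = 1.
- **Kruskal–Wallis** (tie-corrected H, χ² p) for ≥3 groups, with
  **Dunn's** rank post hoc — z = (r̄ᵢ−r̄ⱼ)/√((N(N+1)/12 − T)(1/nᵢ+1/nⱼ))
  with tie term T — and Bonferroni adjustment p·C(g,2) capped at 1.
  Dunn's test is the conventional rank-based post hoc when only
  "Bonferroni-corrected post hoc" is specified. Implemented in-package
  (the formula is small); Kruskal–Wallis itself comes from scipy, so the
  two halves are independently sourced.

Calibration is verified by simulation: under paired and three-group
nulls (2000 replicates, n = 50) both tests reject at 5% within three
binomial standard errors.

## Synthetic phantoms

`make_phantom` builds a geometric stand-in for a maxillofacial CBCT: air
background (−1000 HU), a soft-tissue block (50 HU), a parabolic bone arch
(1200 HU) extruded over the central half of z, and n_teeth tooth units
along the arch — an enamel crown ellipsoid (2800 HU, semi-axes 3×3×4
voxels by default) over a dentin root cylinder (2000 HU, radius 2,
length 6) — plus additive Gaussian noise (SD 30 HU). The ground-truth
mask marks exactly the tooth voxels and is noise-free. Intensities
follow the tissue ordering air < soft < bone < dentin < enamel < metal,
with enamel above the 2500 HU screening threshold and metal (3100 HU)
above 3070, so the MDB screen is exercisable with exact voxel counts via
`add_metal`, which plants metal voxels adjacent to crowns.

`degrade_prediction` turns ground truth into a plausible single-model
prediction with three error modes, applied in order: boundary jitter
(labels in a band of half-width j around the surface flip with
probability 0.25 — a simulation convention producing ragged boundaries),
false-negative dropout (each connected tooth component is partially
eroded with the given probability), and false-positive speckles
(per-axial-slice Poisson counts of radius-1 balls planted clear of the
ground truth). Defaults — 0.5 speckles/slice, radius 1, dropout 0.1,
jitter 1 — are fixed once as a realistic single-model error profile:
speckle-dominated false positives with imperfect boundaries. The
radius-1 speckle default is deliberately smaller than the r = 2
structuring element, making speckle removal by opening provable rather
than statistical.

`simulate_prediction_set` draws one degraded mask per voter. Inter-voter
correlation ρ mixes a shared error realisation with voter-private ones
per voxel (probability ρ of taking the shared error): ρ = 0 gives
independent errors, ρ = 1 with identical configs gives identical voters.
The mixing is a simulation convention, not a claim about how real models
correlate.

**What the phantom shows — and does not.** On it, the five-voter
majority vote's slice-averaged DSC exceeds every individual voter's in
≥95% of replicates (observed: 100%), and opening moves
Sp/PPV up and Sn/NPV down — the qualitative structure of the published
findings. The phantom has no beam hardening, streaks, cone-beam
artifacts, anatomical tooth shapes, or inter-patient variability, and
its teeth are only a few voxels thick at the 64³ test scale, which makes
opening far more destructive to sensitivity than it is on real
512-scale teeth. Passing these tests validates the *machinery*
(decomposition, fusion, morphology, metrics, statistics) and the
*direction* of the ensemble and post-processing effects, not clinical
performance numbers.

## Problem sizes

Tests and the acceptance script run at desk scale, chosen as the
package's own test conditions: 64³ phantoms with 6 teeth for fusion and
post-processing experiments (100 replicates), 32³ phantoms and a
depth-2 / 8-feature 2D network (20 training slices, ≤60 epochs, lr
3e-3 for the reduced variant) for the training demonstration, 12³ masks
for brute-force morphology oracles, and ~10⁶ voxels for the
false-positive suppression law. The full suite completes in well under a
minute on one CPU; `scripts/acceptance.py --seed 1` in about half a
minute.

## Known limitations

- The reference predictor is CPU-bound NumPy; full 512×512 training runs
  are configuration defaults, not something the bundled implementation
  is meant to do at scale.
- No overlap-and-average patch inference, no probability-level
  ensembling, no STAPLE-style weighted fusion (all deliberate
  non-goals).
- Whole-volume DSC is available only as a by-product of summing slice
  counts; surface-distance metrics (HD95, ASSD) are not provided.
- The MDBR count-ratio interpretation, while the only self-consistent
  reading, remains an interpretation; the thresholds are parameters.
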
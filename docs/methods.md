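# Methods

## Problem and approach

`selfseg` implements self-training ("self-annotation") for multi-organ
segmentation of anisotropic 3D grayscale volumes with four organ-at-risk
classes — bladder (1), femoral heads (2), rectum (3), small intestine (4) —
on top of background (0). The premise is label scarcity: expert contours
are expensive, unlabeled volumes are cheap. The pipeline:

1. Split the labeled cases into k = 5 folds; train one U-Net per fold on
   the other four folds, selecting the checkpoint with the best validation
   DSC on the held-out fold.
2. For every unlabeled volume, average the five models' softmax
   probability maps voxelwise ("average voting") and decode labels by
   argmax (ties to the lowest class index, so background wins).
3. Repair the pseudo-labels morphologically: per class, fill enclosed
   cavities, keep the k largest connected components (bladder 1, femoral
   heads 2, rectum 1, small intestine unlimited), optionally close with a
   ball element.
4. Retrain a single model from scratch on labeled + repaired
   pseudo-labeled cases; the same repair is available for its final
   predictions.
5. Evaluate on a held-out test split with DSC, Hausdorff distance, HD95
   and ASD, all spacing-aware (mm).

## Model

Both 2D and 3D U-Nets share the block structure convolution → instance
normalization → leaky ReLU (slope 0.01), two blocks per resolution level,
strided 3×3(×3) convolutions for down-sampling, kernel-2/stride-2
transposed convolutions for up-sampling, skip concatenation, and a final
1×1(×1) convolution to 5 channels with softmax decoding. Channel widths
follow `min(base · growth^level, cap)`. The full presets use six in-plane
down-samplings (256 → 4) with base width 32 capped at 320; the 3D preset
halves z only in the first two stages, so a 32-slice patch bottoms out at
z = 8 — appropriate when slice thickness is ~10× the in-plane spacing.
Output shape always matches the input spatially: a 3D network maps a
(32, 256, 256) patch to (5, 32, 256, 256) class scores, a 2D network maps
(256, 256) to (5, 256, 256).

The network, backpropagation and Adam are implemented directly in NumPy
(float32): convolutions are unfolded im2col-style into one batched matrix
product per layer, and every layer has an explicit backward pass. The
gradient implementation is verified in the test suite against numerical
differentiation (directional derivatives through the whole network, and
elementwise on the loss). On one CPU the 2D test preset (three stages,
base width 8) trains at roughly 10 batches/s on 48² patches; runs are
bit-reproducible for a fixed seed because all randomness flows through one
`numpy.random.Generator` and the arithmetic is single-threaded
deterministic.

## Loss

Training minimizes `L = a·(1 − softDice) + (1 − a)·CE` with `a = 0.5`
(the Dice/cross-entropy weight is not prescribed; 0.5 is the symmetric
default and is configurable). Soft Dice per foreground class is
`(2 Σ p·y + s) / (Σ p + Σ y + s)` with smoothing `s = 1e-5`, averaged over
the four organ classes; a class absent from both prediction and target
scores 1. The printed Dice form is a similarity, so the loss descends
`1 − Dice`. Cross-entropy is the 5-class categorical form
`−(1/n) Σ y ln p` with probabilities clipped at `1e-7`; a channelwise
Bernoulli form is provided for the two-class limit, where it equals twice
the categorical value (each voxel is counted from both channels).
Optional per-class CE weights exist but default to uniform.

Reference full-scale hyperparameters: 250 epochs, Adam, initial learning
rate 0.01 with polynomial decay `(1 − epoch/epochs)^0.9` (the schedule is
a package choice; constant is available), batch 2 at patch [32, 256, 256]
for 3D, batch 12 at [512, 512] (preset, default 256) for 2D, data
resampled to [6.5, 0.664, 0.664] mm. One "epoch" samples as many patch
batches as one pass over the training slices (2D) or patch-grid chunks
(3D), so enlarging the training set proportionally increases optimization
per epoch at a fixed epoch count.

## Preprocessing

Per-image z-score normalization (population sd; constant images map to
zeros) is applied after resampling. Resampling maps voxel centers
`i · spacing` to the target grid with shape
`round(shape · spacing / target)` (round half away from zero), linear for
images, nearest for labels. Patches are sampled uniformly over valid
corners, with a configurable fraction (default 0.33, 0.5 in the pipeline
experiments) centered on a random foreground voxel to oversample organs.
Augmentation applies in-plane crop/pad jitter (±2 voxels) and in-plane
rotation (±15°, linear for images / nearest for labels; multiples of 90°
are lattice-exact). Axis order is (z, y, x) everywhere.

## Post-processing conventions

"Keep the largest components" uses 26-connectivity by default and breaks
size ties by earliest scan-order voxel. Hole filling is volumetric with
face-connectivity background reachability; singleton axes are squeezed
first so a single-slice image behaves as 2D. Closing uses a discrete
Euclidean ball, with the grid padded so border structures are not eroded;
note that the discrete ball's single-voxel tip means a 1-voxel dent in a
flat face is never closed — only concavities narrower than the ball fill.
Classes are processed in index order 1→4 with first-writer-wins conflict
resolution, preserving label exclusivity.

## Metrics

Surfaces are centers of foreground voxels with a non-foreground
face-neighbor (grid edges count as boundary), in physical mm. HD is the
symmetric max–min distance; HD95 the 95th percentile (linear
interpolation) of the *pooled* directed distance sets of both directions
(a convention choice; per-direction maxima are an alternative); ASD the
pooled mean. DSC uses 1 for both-empty and 0 for exactly-one-empty masks;
distance metrics on an empty mask are reported as undefined (NaN +
flag), never silently 0. The expert revision score maps the revised-volume
fraction to six bins (0 → 5, (0, 0.2] → 4, …, (0.8, 1] → 0); the composite
accuracy score is `Σ_organ (DSC + mean expert score / 5)`, with the organ
list configurable because bilateral femoral heads may be counted as one
or two entries.

## Synthetic phantoms

No clinical data ship with the package; a phantom generator emulates the
study conditions. Geometry (per case, jittered): bladder = superellipsoid
(exponent 2.5), femoral heads = two lateral ellipsoids (always exactly two
components), rectum = curved vertical tube, small intestine = chain of
3–8 overlapping blobs. Organs are painted in class order with
first-writer-wins exclusivity. Intensity = per-class mean (bg 0.20,
bladder 0.80, femoral heads 0.50, rectum 0.35, intestine 0.65) + per-class
texture noise (sd 0.08) + global noise (sd 0.10) + smooth multiplicative
first-order polynomial bias field (amplitude 0.15). Each case additionally
draws per-class mean offsets (sd 0.06), emulating the non-quantitative MR
intensity scale. This variability level was calibrated so that a 10-case
supervised model underfits the population — the data-scarce regime
self-training addresses; with weaker inter-patient variability a 10-case
sample saturates and unlabeled data has nothing to add. The rectum radius
(5–8 % of the pelvic extent, ≈ 25–40 mm diameter at full scale) keeps the
thinnest organ resolvable at desk-scale grids.

The phantoms deliberately omit: MR physics (no k-space or relaxation
modeling), organ deformation/contact mechanics, partial-volume effects,
and inter-organ intensity texture correlations. Passing the pipeline tests
therefore demonstrates correctness of the machinery and the direction of
the semi-supervision effect under controlled conditions, not clinical
performance.

`corrupt_labels` produces the raw-prediction error modes the repair stage
removes: in-plane cavities strictly interior to an organ (enclosed also by
the slices above/below — thick slices make 3D spherical cavities
infeasible in thin organs), spherical fragments ≥ 2 voxels away from any
foreground, and boundary flips inside a morphological band. Hole+fragment
corruption (no boundary jitter) is exactly invertible by the repair stage
when component budgets match the clean labels, which the tests verify
voxel-exactly.

## Desk-scale study configuration

Unit and pipeline tests run on reduced problem sizes chosen for a single
CPU: phantom grids of 16×48×48 (pipeline experiments) or smaller (unit
tests) at (6.5, 2.656, 2.656) mm spacing, the 2D test preset (three
stages, base width 8, cap 32), 10 epochs, batch 4, full-slice 48² patches,
foreground oversampling 0.5. The label-budget experiment uses 10 labeled +
30 unlabeled + 10 held-out test cases, with the supervised baseline and
the semi-supervised pipeline sharing seeds, cohort and evaluation
protocol; the semi-supervised gain is averaged over three seeds. The
held-out test split is generated alongside the cohort but never touched by
training or self-annotation.

## Numerical and design choices

* Probability maps must sum to 1 per voxel within 1e-5; sliding-window
  inference blends overlapping windows by uniform averaging, which
  preserves normalization exactly.
* Argmax ties break toward lower class indices (background-conservative).
* Checkpoint selection: best validation DSC when a validation set exists
  (fold models), otherwise final weights (baseline and retrained models,
  which use every labeled case for training).
* The retrained model is a single model trained from scratch on the
  enlarged set, not a re-run of the fold scheme.
* Pseudo-labels are all used; mean max-probability confidence summaries
  are reported but no confidence filtering is applied.
* Fold assignment: random permutation, then round-robin — fold sizes
  differ by at most one, every case validates exactly once.
* Dice smoothing 1e-5, CE clipping 1e-7, instance-norm epsilon 1e-5.

## Known limitations

* The NumPy engine targets desk-scale networks; full-scale presets
  (base width 32, 256² patches, 250 epochs) are defined and functional but
  slow without hardware acceleration.
* Orientation handling of NIfTI input is simplified: spacing comes from
  the header zooms and the affine's rotational part is ignored.
* 3D training works but the anisotropic phantoms and the label-budget
  experiments exercise the 2D path, mirroring the finding that 2D models
  suit thick-slice data better.
* Boundary-jitter corruption is not invertible by design; only
  hole/fragment corruption supports the exact round-trip.
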
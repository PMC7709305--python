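# Methods

This note documents the models, parameters and design choices behind
`oarseg`, and what its phantom-based tests do and do not demonstrate.

## Data model and preprocessing

A case is a 3D HU-valued CT volume with per-axis voxel spacing (mm), a binary
organ mask, a binary body mask, an organ label (SMG/PG) and a laterality.
Arrays use axis order (x = left–right, y = anterior–posterior, z =
inferior–superior), 0-based indices; the lateral flip reverses axis 0 and is
an exact involution.  Under the anatomical symmetry assumption, flipping a
right-sided gland yields an additional left-sided training case.

Preprocessing is a three-step chain:

1. **ROI crop** of a fixed per-organ shape (SMG 64×64×32, PG 96×64×64
   voxels), centered on the organ-mask centroid *rounded to the nearest
   voxel*.  Rounding makes the crop deterministic and exactly
   translation-equivariant (verified by a property test).  Out-of-volume
   regions are padded with the window's lower HU bound — air-like relative to
   the window — and masks with 0.  An organ larger than the crop produces a
   warning, not an error.
2. **HU window** clipping to [center − width/2, center + width/2]; organ
   defaults (−75, 175) for SMG and (−190, 310) for PG.  Idempotent.
3. **Normalization**: affine map sending window lower → 0 and upper → 1,
   then subtraction of the volume mean.  The divisor is the *window width*,
   not the per-volume min/max: after clipping the two generically coincide,
   and fixed bounds keep the map well defined for degenerate (e.g. constant)
   volumes.  Output values lie in [−1, 1] with mean 0.

## Augmentation

Augmentation operates on raw HU volumes (before windowing/normalization),
because the density-shift magnitudes are specified in HU; the pipeline order
is fixed as *augment → preprocess*.

**Traditional** ops — lateral flip, rotation by independent uniform Euler
angles on [0°, 360°) about all three axes (an in-plane-only switch exists),
and additive Gaussian noise (µ=0, σ=15 HU) — each fire independently with
probability 0.5; if none fires the draw is repeated, so an "augmented" copy
is never the identity.  Images are rotated with linear interpolation, masks
with nearest-neighbour so they stay binary and organ ⊆ body is preserved
exactly.

**Domain-specific** augmentation always applies three ops in order:

- *Elastic deformation*: per-axis uniform[−1,1] white noise smoothed by a
  Gaussian of width σ (3.8 SMG / 5.8 PG) and scaled by α (38 / 58), plus an
  affine perturbation of the identity whose linear part receives
  uniform[−1,1]·(affine α)/max(shape) entries (affine α 3.8 / 5.8).  One
  field resamples image (linear) and masks (nearest-neighbour).  The exact
  functional form of the affine term is a design choice; this one makes the
  jitter dimensionless relative to the grid and reduces to the identity at
  α = 0.
- *Body density shift*: one N(0, 100²) HU constant added to all body voxels.
- *Organ density shift*: one N(0, 30²) HU constant added to all organ voxels.

All ops are pure functions of (inputs, seeded generator).  Zero-parameter
limits are exact identities (short-circuited, hence bit-exact).

## Losses and metrics

- **SDC** 2tp/(2tp+fp+fn); the soft variant replaces counts with probability
  sums.  Two empty masks score 1.0 (perfect agreement on absence) with a
  warning — real evaluations never hit this.  No smoothing epsilon by
  default; an epsilon argument exists for empty-reference batches.
- **Weighted SDC(w)** = 2w·tp/(2w·tp+fp+fn): w<1 de-emphasises the interior
  (true positives) relative to surface errors; w ∈ {0.5, 0.05} are the
  studied settings.
- **Hausdorff distance**: symmetric max of directed max–min Euclidean
  distances between foreground voxel centers, in voxel-index units by
  default (physical mm via `spacing=`).  Implemented with KD-tree
  nearest-neighbour queries and tested exactly against an O(n·m) brute-force
  oracle.
- **Combined cost** = dice term + HD/(0.33·x), x = ROI diagonal (96 voxels
  for the SMG crop, so the normalizer is 31.68).  Because the Dice is
  maximized while a cost is minimized, the dice term defaults to
  (1 − soft SDC); a `dice_term="neg_sdc"` flag restores the literal additive
  reading.  The HD enters on the 0.5-binarized prediction as a
  non-differentiable penalty — gradients flow through the Dice term only — 
  with an optional distance-transform soft surrogate.  An empty binarized
  prediction receives the maximal penalty 1/0.33.
- **Contour complexity**: mean over axial slices of (contour length /
  foreground area), with sub-pixel marching-squares contours (pixel-edge
  counting overestimates perimeters and is not used).  A digital disk of
  radius r scores ≈ 2/r; lower = smoother.

## Patient-specific HU windowing

The search grid is centers −100..400 step 10 × widths 100..1000 step 50
(inclusive endpoints, 51 × 19 = 969 windows, center-major scan order).  For
each window the case is re-preprocessed, predicted, binarized at 0.5 and
scored with SDC against the cropped reference; the first maximizer in scan
order wins ties.  Predictions are recomputed per window (no caching), since
the window changes the network input.  The selection criterion requires the
reference contour, so the search is an evaluation/research tool and is
documented as inapplicable to de-novo contouring; learning a scan-to-window
regressor is out of scope.

## Ensembling

Members are binarized individually (threshold 0.5) and vote per voxel; the
ensemble keeps voxels with at least `cutoff` votes.  Probability averaging is
available but not the default, since voting on binarized members matches the
"predict it to be positive" reading.  Cut-off 1 is the union, N the
intersection, and thresholding is antitone in the cut-off (property-tested).
Members differ only in parameter-initialization seed; architectural
diversity and stacking are out of scope.  The default operating point is the
simple majority (⌊N/2⌋+1, i.e. 6 of 11).

## Network and training

The segmentation network is a small 3D U-Net-style fully-convolutional
encoder-decoder written in numpy with manual backpropagation: `depth`
max-pooling stages; two 3×3×3 convolutions (ReLU, inverted dropout) per
resolution level with base_filters·2^i channels; nearest-neighbour
upsampling with skip concatenation; 1×1×1 output convolution and sigmoid.
Convolutions are im2col matrix products, which keeps desk-scale models fast
on one CPU; the full forward/backward chain is verified against finite
differences.  The architecture is configuration, not a constant — scaling it
up is a parameter change.

Initialization is He-style, deterministic per seed (different seeds give
different parameters — the prerequisite for seed-diverse ensembles).  The
output bias is initialised to logit(foreground prior) (default prior 0.1);
starting the predictions at the class balance rather than at 0.5 avoids the
early phase in which soft-Dice training over-corrects the dominant
background, which at higher learning rates can collapse the prediction to
empty (a known failure mode of Dice losses on small structures).

Training uses Adam (default learning rate 1e-3), batch size 1, a random 10%
validation split disjoint from the training subset, and early stopping: the
monitored quantity is the negated validation loss of the configured cost
("higher is better"); when its improvement over the best value so far stays
below 0.001 for 4 consecutive epochs, training stops and the best epoch's
parameters are restored.  The rule is implemented as a pure function of the
metric trace and unit-tested on hand-constructed traces.  Setting
`val_fraction=0` disables the split (and the early stop) — used for
single-case overfit checks.  Dropout is active only during training;
inference is deterministic.

Dropout rate, learning rate, batch size and filter counts are exposed
configuration with desk-scale defaults (see below); no claim is made that
they match any particular clinical-scale setup.

## Phantom generator

The generator emulates the statistical structure the toolkit assumes about
head-and-neck CT: an elliptical body (soft tissue N(40, 15²) HU) on air
(−1000 HU); one gland-like organ — an ellipsoid with uniformly drawn
semi-axes, offset to the requested side of the midline, its implicit surface
perturbed by a smooth Gaussian random field (irregularity amplitude 0.3) so
every case has its own shape; organ tissue N(55, 10²) HU, i.e. a 15 HU mean
contrast with heavily overlapping histograms (Bhattacharyya coefficient
≳ 0.8, asserted > 0.3) — the organ is deliberately hard to see; an optional
bone-like rod (700 HU); and independent Gaussian image noise (5 HU).
Defaults: 128×128×64 grid at 1×1×2.5 mm spacing;
`PhantomConfig.desk_scale()` shrinks the grid to 32×32×16 with
correspondingly smaller glands.  Ground-truth masks are exact by
construction and generation is a pure function of (config, seed).

What the phantom does *not* emulate: anatomical surroundings (multiple
organs, mandible geometry, skin), metal artifacts, scanner-specific noise
texture, inter-observer contour noise, and the true difficulty of gland
boundaries against muscle.  Passing phantom experiments therefore
demonstrates that the *machinery* (losses, augmentation, windowing, voting,
cross-validation bookkeeping) behaves as designed and that the qualitative
strategy effects can materialise — not that clinical-scale Dice values are
reproduced.

## Experiment designs and desk-scale sizes

All designs use six-fold cross-validation: every case appears in exactly one
test fold, train = complement.  Augmented copies are drawn (with
replacement) only from the fold's own train cases and inherit its fold — no
augmented derivative of a test case ever reaches training.  Controlled
comparisons (cost functions; combined-pipeline arms) share fold plans and
initialization seeds so the studied factor is the only difference.
Aggregates pool all folds' per-case rows and report mean ± sample SD (n−1);
SDC is formatted to two decimals, HD to one.

The desk-scale preset (`desk_scale_setup()`) is: 32×32×16 phantoms, 12×12×8
ROI crop, depth-2 network with 8 base filters and dropout 0.1, Adam 1e-3,
up to 30 epochs, cohorts of 18–24 cases, 5-member ensembles, and a coarse
sub-grid of the window search (center step 50, width step 150) inside the
combined pipeline.  These sizes were chosen once so that a full six-fold
design completes in seconds to a few minutes on a single CPU while still
being large enough for the directional effects to be measurable; the
clinical-scale values (full 969-window grid, 11-member ensembles, 64×64×32
and 96×64×64 crops) remain the library defaults of the corresponding types.

The clinical-data-dependent parts of the original protocol are out of scope
by design: voxel-level contour curation is a manual activity (the contour
complexity score supports analysing such data when a user supplies clinical
and curated contour pairs), and clinical-cohort results are not
reproducible from synthetic data.

## Known limitations

- The numpy network is desk-scale; it is not intended for 512×512 clinical
  grids (an epoch on full-size SMG crops is possible but slow).
- The HD term of the combined cost contributes no gradient (binarized,
  non-differentiable); training signal differences between SDC and SDC+HD
  are therefore mediated by early stopping and the loss landscape only — the
  soft-HD surrogate can be enabled to study a differentiable-in-spirit
  variant.
- Rotation "in all angles" treats the volume as isotropic; with 2.5 mm
  slices a physically correct rotation would resample anisotropically.
- The one-voxel dilation tolerance in the elastic-deformation containment
  test reflects nearest-neighbour resampling at mask boundaries.
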
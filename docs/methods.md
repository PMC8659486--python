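# Methods

This note documents the models, the synthetic data, the numerical choices
and the open design decisions behind `renalseg`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Data model

A scan is a `DceSeries`: a float32 array indexed `(t, z, y, x)` with
strictly increasing acquisition times (seconds from injection) and voxel
spacing `(dz, dy, dx)` in millimetres. `z` indexes the coronal slice — the
depth `D` over which the compartment rules iterate. On disk the package
reads and writes 4D NIfTI in `(x, y, z, t)` order via nibabel, with a JSON
sidecar carrying times and spacing when the header cannot. The canonical
acquisition geometry is 32 coronal slices of 224×224 at 1.25×1.25×3 mm and
~50–150 frames over six minutes; nothing in the code assumes those numbers
beyond defaults.

Compartment labels use a fixed legend: 0 background, 1 medulla, 2 cortex.
Bounding boxes are inclusive per-axis index ranges; an absent kidney is a
`present=False` box of exactly one voxel, and every consumer treats such a
box as "skip this side" rather than an error.

## Preprocessing

Network input is a 5-channel 64³ tensor per scan (or per crop):

1. **Temporal resampling** — per-voxel linear interpolation onto a uniform
   grid over `(0, 300]` s (50 samples by default), clamped to the nearest
   acquired frame outside the acquired range. Linear interpolation is
   exact for affine-in-time signals, monotone and cheap.
2. **PCA channel reduction** — each voxel's time course is one sample of a
   `T`-dimensional feature space; the top 5 eigendirections of the
   time–time covariance (fitted per scan, `covariance_eigh` solver) become
   the channels, ordered by decreasing explained variance. Component sign
   is fixed by making each component's largest-magnitude loading positive,
   so channel images are reproducible across runs and platforms.
3. **Spatial downsampling** — trilinear (`order=1`) resampling to 64³;
   labels use nearest-neighbour (`order=0`) to preserve integrality.
4. **Rescaling** — linear map of `[min, max]` to `[0, 255]`; a constant
   volume maps to 0.

Augmentation draws a per-axis integer translation with magnitude in
`[1, 4]` voxels (random sign) and an isotropic zoom in `[0.96, 1.04]`,
applied identically to image (trilinear) and label (nearest). The zoom
bounds are a design choice: the translation range is given in pixels, the
scaling range is not, and ±4 % keeps the transform of the same order as a
4-voxel shift at 64³.

## Networks and training

**Localiser (3D Rb-UNet).** Four encoder blocks of two 3×3×3 conv+ReLU
with an additive identity shortcut from block input to output (1×1×1
projection when channels differ), each followed by 2×2×2 max-pool stride 2
and dropout; a two-conv bottleneck with dropout between; then five decoder
blocks. Four of them upsample (2×2×2 transposed conv stride 2), concatenate
the equal-scale encoder features and apply a residual double-conv; the
fifth is a full-resolution residual refinement block without upsampling —
with four pooling stages there are only four scales to climb back through,
so the fifth decoder block operates at full resolution ahead of the batch
norm + 1×1×1 head to 3 classes (background / right / left). Base filter
count is 32, doubling per scale (config).

**Segmenter (3D FC-DenseNet).** Initial 3×3×3 conv (48 filters), six dense
blocks of 4, 5, 7, 10, 12, 15 layers (each layer BN → ReLU → 3×3×3 conv of
growth-rate 12 channels → dropout, input concatenated to output), a
transition-down after each of the first five (BN → ReLU → 1×1×1 conv with
channel reduction 0.8 → dropout → 2×2×2 max-pool **stride 2** — a stride-1
pool would not reduce resolution and could not meet a five-stage
upsampling path, so stride 2 is used), five transition-up blocks (3×3×3
transposed conv, stride 2) each carrying only the preceding block's newly
produced features, concatenated with the equal-scale skip and followed by
dense blocks of 12, 10, 7, 5, 4 layers, and a 1×1×1 softmax head over
kidney / non-kidney.

**Loss.** Class-weighted per-channel binary cross-entropy over softmax
outputs, averaged over the number of voxels `N` (times the batch size):
every channel term of voxel `i` is weighted by the class weight of the
voxel's *true* class, inversely proportional to that class's voxel prior
and normalised so background weighs 1. Probabilities are clamped at
`ε = 1e-7` before the logarithm. The summation convention — all `N` voxels
per channel, averaged by `N` — is the only reading under which `N` is "the
number of voxels in a volume".

**Optimisation.** Adam, initial learning rate 1e-4, halved every 50
epochs, weight decay 1e-8, dropout 0.2, batch size 4, up to 400 epochs —
the full-scale defaults. Batch-norm running statistics use momentum 0.9.
Training is deterministic for a fixed seed: one `numpy` generator drives
initialisation, batch order and dropout.

**Desk-scale configurations.** Tests and the acceptance script shrink the
problem through config only, never through the architecture's layout:
16×64×64 phantoms with 12 frames, 32³ network input, localiser base
filters 4, segmenter growth 4 / initial filters 48→8, dropout 0, learning
rates 1e-3–3e-3 (standard for such small networks), 5–12 epochs, batch 2.
At these sizes the full suite and the acceptance run fit comfortably on a
single CPU. The engine releases each step's graph and intermediate
gradients eagerly, bounding resident memory at well under 1 GB for the
desk-scale runs.

## Compartment segmentation rules

The rule stage assumes the cortex is brighter than the medulla during (at
least) the early-to-mid acquisition, and operates per kidney on masked
slices: background is zero, and all statistics (unique intensities, Otsu
histogram) consider only non-zero pixels — otherwise the threshold would
separate kidney from background instead of cortex from medulla.

- **Depth ranges.** Central slices are `p_f = floor(r_f·D)` through
  `p_l = round(r_l·D) − 1` (0-based, clamped), with `r_f = 0.3`,
  `r_l = 0.7`. Central slices get the intensity shift (strictly interior
  intensities reduced by the slice minimum `a_min`); peripheral slices get
  the gamma correction `(s/255)^γ·255` (computed ratio-first in float64 so
  large γ cannot overflow).
- **Gamma.** Default γ = 1.5. A much larger range (γ up to ~74) appears as
  an alternative operating regime; both are plain config values, and the
  default follows the tuned operating point.
- **Sigmoid.** `E(s) = 1/(1 + exp(δ(μ − s)))` with gain δ = 2 and cut-off
  μ = 1.5 applied to intensities rescaled to `[0, 1]`; since μ > 1 the
  curve is a monotone contrast remap rather than a symmetric S around a
  mid-grey. The output is mapped to `[1, 255]` — not `[0, 255]` — so the
  darkest tissue never collapses into the zero background sentinel.
  Monotonicity guarantees the cascade permutes no intensity ordering, so
  Otsu classes are intervals of the original intensities.
- **Otsu.** Candidates are the unique non-zero values; the threshold
  maximises `σ_b²(τ) = ω_0 ω_1 (μ_0 − μ_1)²` with the split `≤ τ` vs
  `> τ`; ties resolve to the lowest maximising threshold. A constant
  region yields an all-zero binarisation and a logged warning.
- **Per-slice labelling.** The kidney mask slice is "fully closed" —
  morphological closing with a disk of radius 2 (1.25 mm in-plane pixels)
  to bridge small gaps, then binary hole filling; candidates outside the
  closure are discarded; inside the kidney, dark pixels become medulla and
  bright pixels cortex (bright pixels in the closure's filled-in region
  also count as cortex).
- **Temporal fusion.** The reference labelling is the frame at
  `t_x = round(x·T)` with `x = 0.375` — the midpoint of the sensible
  `[0.25, 0.50]` window, early enough that cortex still leads medulla.
  For central slices, reference cortex pixels are demoted to medulla where
  some frame labels them medulla *and* that frame's slice has a plausible
  medulla share (`α = 30 < rMA < β = 60` percent).
- **Cortex refinement.** `Θ_tx(d)` is the *fully closed* cortex-candidate
  slice at the reference frame — the filled cortex contour (the only
  binarised per-time object the algorithm constructs). Medulla claimed
  outside that contour reverts to cortex: this rescues degenerate
  pure-cortex slices whose constant intensity defeats Otsu, and demotes
  medulla leaking past the enhancing parenchyma, while leaving interior
  medullary pyramids — holes in the cortex ring, filled by the closure —
  untouched. Hole filling rather than fixed-radius closing is essential:
  real pyramids are far larger than any reasonable closing radius, and a
  radius-bounded closure would misclassify their interiors wholesale. The
  whole-kidney rim (dilation minus erosion with a radius-1 disk) is
  labelled cortex. Finally labels are clipped to the fully closed kidney
  mask, which keeps the rim rule from painting outside the organ.
- **Two kidneys.** Processes run independently per side and merge by
  union; the masks are disjoint so labels cannot collide.

## Synthetic phantoms

The generator emulates the statistical structure the pipeline assumes, not
MR physics:

- **Geometry.** One or two ellipsoidal kidneys either side of the
  sagittal midline (patient-left at high x), with a cortical shell of
  `cortex_thickness` (default 2) voxels. Size, position and lobe count
  vary with the seed, emulating the anatomical spread of a paediatric
  cohort: semi-axes drawn from 0.36–0.44·D (kidneys span most of the
  coronal stack, so the central slice range cuts through parenchyma),
  0.19–0.25·H and 0.095–0.125·W, centres jittered by a few percent, and
  2–4 medullary lobes per kidney (fixable via config). The interior
  defaults to cortex (columns); medulla is a set of rod-shaped lobes
  strung along the long axis, elongated through z, with in-plane radius
  `cortex_thickness + 1` so every medulla voxel keeps a cortex voxel
  within Chebyshev distance `cortex_thickness + 1`.
- **Kinetics.** Cortex: baseline 40, amplitude 170, time-to-peak 40 s,
  washout 0.004/s; medulla: 30 / 60 / 90 s / 0.003/s; background level 20
  (all on the `[0, 255]` display scale). The curve rises as a half-sine to
  the peak and decays exponentially towards baseline. With these defaults
  the cortex outshines the medulla at every frame — the contrast ordering
  the rule stage relies on — and cortex peaks 50 s before medulla, as in
  real cortico-medullary transit.
- **Noise and artefacts.** Additive Gaussian noise (default σ = 4) or
  Rician (magnitude of a complex Gaussian), seeded; optional zero-mean
  radial spoke patterns (stack-of-stars streaking) and per-frame Gaussian
  blur (breathing). Zero amplitudes are exact identities.
- **Abnormalities.** `missing_kidney` drops the left kidney;
  `dilated_pelvis` carves a non-enhancing central cavity out of the left
  kidney's mask and labels, mimicking a dilated collecting system.

What the phantoms do *not* emulate: partial-volume mixing at tissue
boundaries, spatially varying coil sensitivity, respiratory motion fields,
tracer physics, or anatomical variability of real kidneys. Passing the
phantom-based tests therefore demonstrates the pipeline's mechanics —
contracts, invariances, recovery under its own assumptions — not clinical
accuracy; cohort-scale numbers require real annotated data.

## Numerical and degenerate-input conventions

- Otsu on fewer than two distinct values: all-zero output, flagged.
- `rMA` undefined on empty slices; such slices are skipped in fusion.
- Metrics: both volumes empty → scores 1 with a warning; empty prediction
  against non-empty truth → precision 0 (and DSC 0 through the union
  denominator). Cohort SD is the sample SD (ddof = 1), 0 for singletons.
- Curve baseline `I_0` is the first acquired frame's mean; a zero baseline
  falls back to absolute differences.
- Max-pool gradients split evenly among tied maxima (deterministic);
  PCA of a zero-variance series returns zero ratios without error.
- Localisation training targets: connected components of the whole-kidney
  mask assigned right/left by centroid against the mid-x plane.
- `predict_boxes` pads the mapped-back box by one coarse-grid cell,
  absorbing the quantisation error of nearest-neighbour downsampling.

## Known limitations

- The numpy engine is single-threaded GEMM-bound; full-scale (64³,
  growth 12) training is feasible but slow — the desk-scale configs are
  the intended regime for development and CI-style verification.
- On noise-free phantoms the rule stage recovers both compartments
  exactly (two-valued slices are exactly Otsu-separable); the informative
  regime is noisy data, where the medulla degrades before the cortex —
  the ordering clinical cohorts also show. Per-slice Otsu remains the
  weak point when in-slice cortico-medullary contrast collapses at some
  frames; the temporal fusion exists precisely to bridge those frames.
- Left/right assignment assumes kidneys do not cross the mid-sagittal
  plane; ectopic or horseshoe anatomy would need an explicit mask input.
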
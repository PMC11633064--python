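# Methods

## Problem and model

The package detects mandibular fractures in CBCT volumes with a cascade of
three patch-based networks: (1) mandible segmentation with an auxiliary
patch-position regression, (2) fracture-line segmentation on the
mandible-cropped scan by two cascaded U-Nets, (3) patch-level fracture
classification. Scan-level results come from tiling with 50 % overlap,
overlap-averaging voxel predictions, interpolating patch-level
probabilities, extracting connected components as proposals, uniting
overlapping proposals from stages 2 and 3, and excluding low-confidence
proposals. The assumptions are those of the cascade itself: the mandible is
a single bright structure a segmenter can find; fracture evidence is local
enough to live inside a 64³ patch; and the union of a high-precision
voxel-level detector with a high-sensitivity patch-level detector is a
better proposer than either alone.

## Conventions fixed by this package

Several details are not forced by the cascade design and are fixed here as
package conventions:

- **Working grid.** All pipelines resample to 0.4 mm isotropic voxels
  (typical CBCT resolution) before patching; output dimension per axis is
  `round(dim·spacing/target)`. Voxel indices are 0-based, axis order
  (x, y, z) as stored in the NIfTI array; patch origins are inclusive
  corner indices.
- **Intensity baseline.** CBCT has no calibrated HU scale, so each volume
  is clipped to its (0.5, 99.5) percentile interval and rescaled to [0,1].
- **Adaptive windows.** The three extra input channels clip the patch to
  its per-patch percentile intervals (0–40), (30–70), (60–100) over valid
  (non-padded) voxels, then rescale each to [0,1] — overlapping windows
  emphasising soft tissue, cancellous and cortical bone. A collapsed
  window yields an all-zero channel.
- **Tiling stride.** 32 voxels (50 % overlap) for inference; training
  patches are randomly positioned, half of them centred on structure
  (mandible voxels for stage 1, fracture voxels for stages 2–3) so that
  minibatches see foreground early.
- **Position target.** The patch-centre index divided by (dim − 1) per
  axis, clipped to [0,1]; axes of size 1 map to 0.5. Using the centre
  keeps the target symmetric and bounded under clamped origins.
- **Softened fracture targets.** Binary dilation with a radius-1 ball then
  Gaussian filtering with σ = 0.5 voxel, peak-renormalized to 1. This
  grows the positive set of a thin plane roughly 3–7× while keeping the
  plane's crest at full weight. Both knobs are exposed.
- **Proposal extraction.** Binarization threshold 0.5 for both maps,
  26-connectivity (thin oblique planes fragment under face-connectivity),
  minimum size 10 voxels, confidence = mean stage-2 probability over the
  proposal, default confidence cut 0.5 (the FROC sweeps it). Stage-3
  evidence outside the 3-voxel-dilated predicted mandible is discarded —
  the detector's remit is mandibular fractures, and this curbs
  interpolation spill. Crop margin around the predicted mandible: 10
  voxels.
- **Stage-3 interpolation.** Per-patch probabilities sit at patch centres
  and are interpolated trilinearly; border voxels outside the centre
  lattice take the nearest lattice value. Thresholding happens after
  interpolation.
- **Detection matching.** A proposal hits a ground-truth fracture if it
  intersects the fracture dilated by 2 voxels (absorbing one-voxel
  boundary disagreement on thin planes); assignment is greedy by
  descending confidence, one match per side. Degenerate denominators
  (no proposals / no fractures) report 1.0 with a flag instead of raising,
  so batch evaluation never aborts. The FROC summary takes, at each FP/scan
  budget in {1/16, 1/8, 1/4, 1/2, 1}, the best sensitivity at or below the
  budget (step-function convention) and averages the five values.

## Training recipe

AdamW with weight decay 0.01; mini-batch 4; base learning rates 0.005
(stage 1) and 0.002 (stages 2–3); linear warmup over 5 % of the epoch
budget then cosine annealing to zero; at most 500 epochs at full scale.
An epoch is `patches_per_epoch` randomly drawn patches (default 256)
rather than an exhaustive pass — no canonical epoch exists over random
patches. Stage 1 trains on scans with complete (unfractured) mandibles,
stages 2–3 on fractured scans; earlier stages are frozen in evaluation
mode while later ones train (the cascade is wired strictly sequentially,
and the frozen-prior contract is tested: stage-1 parameters stay
bit-identical through stage-2 training). Model selection keeps the
parameters of the epoch with the lowest validation loss; since the stopping
criterion for "maximum of 500 epochs" is otherwise unspecified, training
runs the full budget and selects afterwards. Stage 1's two losses are
summed with equal weight (no weighting is prescribed); probability clamp
for cross-entropy is 1e-7.

## Architecture

U-shaped networks with conv(3³)–batchnorm–leakyReLU(0.1) blocks (two convs
per block), 2× max-pooling between resolution levels, nearest-neighbour
upsampling followed by a conv block in the decoder, concatenation skip
connections, and a 1×1×1 logit head. Default: 4 levels, base width 16,
doubling per level. Nearest-upsample + convolution was chosen over a
transposed convolution: it plays the same role with simpler exact
gradients in the package's own autodiff engine and avoids checkerboard
artifacts. The position and classification heads are GAP over the deepest
encoder features → 64 hidden units → output (3 sigmoid units for position;
1 logit for classification). The stage-1 decoder features forwarded to
stages 2–3 are the decoder's final hidden layer (width = base width); the
channel count of every concatenated input is recorded in the architecture
descriptor, and checkpoints embed the descriptor and refuse to load into a
mismatched model.

The networks run on `mandfrac.nn`, a compact numpy reverse-mode autodiff
engine. 3D convolution uses an im2col + matrix-product path on small grids
and an exactly-equivalent FFT path on large grids (circular convolution at
length ≥ S+2 with spatially flipped kernels; the input transform is reused
for the weight gradient). Both paths are cross-checked against each other
and against finite differences in the unit tests.

## Synthetic phantoms

The generator emulates the data regime the detector is built for: a
mixed cohort of fractured and intact mandibles with exact voxel ground
truth. The mandible surrogate is a half-torus ("horseshoe", arch radius
12 mm, tube radius 4 mm) with a bright cortical shell (0.9), dimmer
cancellous interior (0.5), dark background (0.15), additive Gaussian noise
(σ = 0.03), 96³ voxels at 0.4 mm. Fracture planes cross the arch roughly
transverse to its local tangent:

- *nondisplaced*: bone voxels within 0.4 mm of the plane are depressed to
  background intensity and form the ground-truth mask;
- *displaced*: all bone on one side of the plane is rigidly translated
  2.4 mm along the normal (rounded to a whole-voxel offset so masks stay
  exact); the ground truth is the one-voxel interface band on both cut
  surfaces. At most one displaced fracture is planted per phantom — a
  second rigid shift would compound with the first and fragment the
  geometry.

Planes are kept ≥ 0.3π of arch angle apart and local to a sphere of 3 tube
radii around the plane point (an infinite plane would otherwise graze the
opposite arm of the horseshoe). Intensities are ordered background <
cancellous < cortical by construction, one master seed derives per-scan
seeds as `seed + index`, and identical spec + seed is bit-identical.
Stratified 60/20/20 splitting uses the scan's fracture-kind stratum
(none / nondisplaced / displaced / mixed) with largest-remainder rounding;
the clinical subregion taxonomy (median … condyle) has no phantom analogue.

What the phantoms do **not** emulate: CBCT physics (beam hardening,
scatter, metal streaks), anatomy (teeth, condyles, cortical thinning),
intensity inhomogeneity, or the hard fracture phenotypes (hairline cracks
at noise level). Phantom results therefore demonstrate that the pipeline's
machinery — sampling, cascading, fusion, evaluation — is correct and
trainable, not that the model reaches clinical accuracy; the clinical
numbers reported for this architecture come from GPU training on hundreds
of annotated scans, which the package does not claim to reproduce.

Stage 2 is trained here against all planted fracture voxels (both kinds):
in the phantom the displaced interface band is a thin low-intensity
structure exactly analogous to a nondisplaced fracture line, so
restricting stage-2 supervision to nondisplaced cases would discard
learnable signal that the clinical setting reserves for stage 3.

## Desk-scale reference experiment

`mandfrac.smallscale` fixes one scaled-down configuration: width-4
networks with 3 levels, 32³ patches, 14 training / 6 validation phantoms
(half fractured), 5 held-out fractured phantoms; 15/10/8 epochs for stages
1/2/3 at 64 patches per epoch. These sizes were chosen once as the
smallest configuration at which each stage's task remains learnable above
its brute-force baseline (a fixed intensity threshold inside the bone,
which on noise-free phantoms recovers both the mandible and nondisplaced
fractures nearly perfectly — the learned pipeline is required to reach
Dice ≥ 0.8 and sensitivity ≥ 0.8 at ≤ 1 FP/scan, below what that baseline
suggests is attainable). The experiment is seeded end to end; variation
across seeds comes from phantom noise, patch sampling and weight
initialization.

## Known limitations

- The cascade's stage-2/3 context concatenates frozen stage-1 features;
  no joint fine-tuning is implemented (the design is strictly sequential).
- Proposals are not typed (nondisplaced vs displaced), matching the
  detector's scope; per-kind sensitivity is only computable where kind
  labels exist (the phantom manifest supplies them).
- Batch normalization uses running statistics in evaluation mode; training
  with batch size 4 makes those statistics noisy at the margins.
- The FFT convolution path assumes stride 1 and 'same' padding; the
  engine supports exactly the operations the cascade needs, nothing more.
- `read_volume` rejects scans with unknown or non-positive voxel spacing
  rather than guessing (mirroring the exclusion applied to the clinical
  cohort); 4D series and DICOM ingestion are out of scope.
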
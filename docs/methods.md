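# Methods

This note documents the models and procedures implemented in `fundus2cfi`,
the parameters that matter, the design decisions taken where the design was
genuinely open, and what the phantom-based evaluation does and does not
establish.

## Scaled feature registration

**Step 1 — OD scale adjustment.** The optic disc is the most stable bright
landmark shared by ultrawidefield (UFI) and conventional (CFI) fundus images,
and its apparent size calibrates the scale gap between the two fields of
view. The detector is an interface; the default is a classical bright-blob
detector (grayscale → Gaussian smooth, sigma 2 px → threshold at the 99th
brightness percentile → connected components → highest-confidence bounding
box, ties broken toward larger area then smaller (y, x)). A learned detector
can be plugged in through the same one-method contract; the oracle detector
replays a known box, which is how phantom ground truth enters tests. The crop
window is six times the OD box, centered on it; when the window crosses a
border it is shifted inside rather than shrunk (preserving OD-relative
scale), and clamped only when it exceeds a whole image dimension.

Resampling convention: the crop-to-`l` resize and the keypoint map use the
same corner-anchored affine — output pixel `s` reads the crop at
`s · crop_side / l` — so a point mapped through the affine lands exactly on
the feature it indexes in the resampled raster. A Gaussian anti-alias filter
(sigma = factor/2) precedes any downscaling. Coordinates are 0-based, x =
column, y = row, pixel centers at integers, in every module.

**Step 2 — feature registration.** Grayscale is BT.601 luma. The default
matcher is ORB (800 keypoints, FAST threshold 0.02, Hamming cross-check);
SIFT (Lowe ratio 0.75, cross-check) is available, and the backend protocol
accepts any callable returning matched point sets, so a learned graph-based
matcher can be slotted in without code changes. Homographies are estimated by
RANSAC over 4-point normalized-DLT (Hartley normalization) solves —
reprojection threshold 3 px, at most 2000 iterations with an adaptive bound
at confidence 0.995, seeded — followed by a least-squares DLT refit on the
inlier set. Near-collinear minimal samples are rejected by a triangle-area
test.

Feature detectors localize keypoints to roughly a pixel, which bounds the
accuracy of any purely point-based estimate; at a 128-px working resolution
that is not enough for OD-radius-relative evaluation (θ = 0.15 of a ~7.7 px
OD radius is ~1.2 px). `register` therefore finishes with an intensity-based
polish: the source is warped under the current estimate, residual sub-pixel
shifts between Hann-windowed warped/target patches are measured by phase
correlation on a control-point grid (textured patches only), each shift is
converted to a correspondence, and the homography is refit by trimmed least
squares. A coarse pass (32-px patches, ±8 px search, 3 iterations) absorbs
initializations several pixels off; a fine pass (16-px patches, ±3 px, up to
8 iterations, stopping when the mean measured shift falls below 0.03 px)
converges well below half a pixel when the projective model holds. On
phantoms this yields mean ground-truth reprojection errors of 0.03–0.25 px.

The validity mask is the warped footprint of an all-ones raster thresholded
at 0.5; it deliberately does not exclude dark UFI corners (the warp footprint
is the only region where "valid overlap" is well defined without additional
conventions).

## PCK evaluation

PCK counts index-matched annotated keypoints whose mapped position lies
strictly within τ = θ·r of the annotation, with Euclidean distance and r the
mean OD radius of the evaluation set, fixed here as the mean OD-box
half-width in pixels. The strict inequality is kept even though ties have
measure zero. Points whose homogeneous coordinate collapses (|w| < 1e-12)
count as incorrect.

## Translation model

Inputs are registered UFI/CFI pairs in [0, 1] RGB. Three networks:

* **Correction branch F** — `correction_blocks` (default 4) conv3×3 +
  instance-norm + ReLU blocks and a 1-channel sigmoid head, predicting a
  vessel edge map in [0, 1].
* **Generator** — the UFI and edge map are concatenated (4 channels). The
  global path G1 average-pools the concatenation 2×, applies a conv block and
  `res_blocks_global` residual blocks (reference configuration 9). The local
  encoder G2E applies a conv block, a stride-2 conv, and `res_blocks_local`
  residual blocks (reference 3). Both emit feature maps at half resolution
  and equal width; they are fused by element-wise addition and decoded by G2D
  (2× nearest upsampling, conv blocks, sigmoid head) into the synthetic CFI.
  An alternative description of the same family places 16 residual blocks in
  the generator; the 9+3 split is used as the concrete default and both
  counts are configuration keys.
* **Discriminator** — a conditional patch critic on the 6-channel
  (condition, candidate) concatenation: `disc_layers` (default 3) stride-2
  conv4×4 layers with instance norm and LeakyReLU(0.2), then a 1-channel
  conv3×3 head. The output is a spatial grid of per-patch logits (16×16 on a
  128-px input); "7×7 patches" is read as the granularity of this patch
  grid, not a literal image tiling.

Normalization is non-affine instance norm throughout; generator
nonlinearities are ReLU, final activations sigmoid so outputs and edge maps
live in [0, 1]. Networks run on a small numpy NCHW engine with manual
backprop (`_nn.py`): convolutions as k² shifted matrix products, explicit
backward passes, Adam with per-parameter moments. At desk scale (side 64,
8–16 filters) a full generator+discriminator step takes ~0.4 s on one CPU.

## Losses and optimization

* Adversarial: binary cross-entropy on logits in the log form
  (discriminator: real-vs-1 plus fake-vs-0; generator: fake-vs-1), averaged
  over the patch grid.
* Reconstruction: mean absolute difference. When a registration mask is
  present the L1 term is restricted to it (config-controlled, on by default)
  so zero-filled warp exteriors do not dominate.
* Correction: mean squared difference between the predicted edge map and the
  Laplacian target h(y): BT.601 grayscale convolved with the 4-neighbour
  kernel [[0,1,0],[1,−4,1],[0,1,0]] under reflect padding, absolute value,
  scaled by 1/4 (the kernel's peak response to a unit step) and clipped to
  [0, 1] — so target and prediction share a range.
* Total: `L = L_cGAN + λ1 L1 + λ2 L_corr`, λ1 = 100 (paired image-to-image
  convention), λ2 = 10 (one order below, for an already-small-magnitude MSE
  term). Both are configuration.

Optimization is Adam (β1 = 0.5, β2 = 0.999), learning rate 2e-4, constant
for `epochs_constant_lr` epochs then linearly decayed to zero at
`epochs_total` (reference 100 + 100). Each batch takes one discriminator step
(fake detached) and one generator+correction step; F is trained jointly
through the single objective, receiving both the correction-loss gradient
and the gradient flowing through the generator's edge input. Training is
deterministic given the seed; per-epoch means of every loss term are
recorded, checkpoints (weights + optimizer moments) support exact resumption,
and the first non-finite loss term aborts with its name.

## Phantom generator

The generator emulates the structure that the method depends on, not
photorealism. A scene is rendered once in the CFI coordinate frame on an
extended canvas: orange-red background with radial falloff; low-frequency
choroidal mottling; ~70 punctate drusen-like/pigment blobs (radius 2.5–5 px
at size 128) that give feature detectors well-distributed anchors, as real
fundus texture does; a bright OD ellipse with a paler cup; a darker macular
blob; and a vessel tree grown by a recursive branching random walk from the
OD rim (width-tapering, branching more often near the disc as real arcades
do, with a global length budget that keeps vessel coverage at 2–15% of the
field). Branch points are the ground-truth keypoints.

The UFI is the same scene resampled through a sampled projective embedding —
scale 1.6–2.2 (of the admissible [1.5, 4]), rotation ±15°, small projective
jitter — followed by UFI-specific degradations: channel gains (0.9, 1.1,
0.5) mimicking pseudo-color, Gaussian blur around the macula, additive noise
(sigma 0.01), dark peripheral arc artifacts, and a circular field-of-view
vignette. The default embedding scale sits at the lower end of the admissible
range because the default working resolution (128 px, vs 512 px for a
realistic clinical pipeline) leaves proportionally less detail per OD radius;
at 128 px a ~2× scale gap stresses the matcher comparably to a ~4× gap at
512 px. Ground truth: the homography from scale-adjusted-UFI coordinates to
CFI coordinates is the composition of the (known) embedding with the crop
affine computed from the ground-truth OD box, so keypoint correspondences are
exact to floating-point; the generator regrows the vessel tree (up to 10
attempts, same seeded stream) if fewer than 8 bifurcations survive the
shared-visibility filters, and keypoint counts are truncated to 8–24.

What phantoms do not model: pathology morphology (drusen here are generic
blobs, not clinically graded lesions), mosaicking optics, non-planar retinal
geometry (the true transform is exactly projective, which real eyes only
approximate), and illumination/contrast variability between devices. Passing
tests therefore establish correctness of the geometry, losses, and training
mechanics, and directional behaviour of the pipeline — not clinical image
quality.

## Evaluation metrics

MSE and PSNR are computed on 0–255-scaled intensities (PSNR =
10·log10(255²/MSE), +inf sentinel at MSE 0). SSIM is the reference
formulation (11×11 Gaussian window, sigma 1.5, K1 = 0.01, K2 = 0.03, dynamic
range 255), channel-averaged; MS-SSIM accumulates contrast-structure terms
over up to 5 dyadic scales with the standard weights (0.0448, 0.2856,
0.3001, 0.2363, 0.1333), adds luminance at the coarsest scale, and reduces
the scale count with renormalized weights (and a warning) when the image
cannot support a 11-px window at the coarsest scale. Masked variants restrict
MSE/PSNR and the SSIM-map average to a supplied validity mask.

## Desk-scale study configurations

The reference training configuration (512 px, batch 64, 64 filters, 200
epochs) is expressible in configuration but not exercised by the test suite;
the tested problem sizes are:

* *Training smoke*: one registered phantom pair, side 64, 16 filters, 2+1
  residual blocks, 200 iterations. The generator's L1 term falls by ~90% and
  the generated image exceeds the identity baseline in SSIM.
* *Ablation*: 6 phantom pairs, side 64, 8 filters, ~120 iterations per cell,
  2×2 grid {registration on/off} × {correction branch on/off}, 3 seeds.
  Registration-on cells use the ground-truth warp of the scaled UFI (ideal
  registration) with masked L1; correction-off cells feed a zero edge map
  and drop λ2. All four cells of a pair are evaluated on the same
  valid-overlap mask. Registration dominates: its cells win MSE in every
  seed, with MSE roughly halved. The correction branch's SSIM increment is
  small at this scale and wins or ties only in a majority of seeds — at desk
  scale edge guidance is a second-order effect, consistent with registration
  being the prerequisite and the branch a refinement.

## Known limitations

* The intensity-refinement stage assumes the residual misalignment is
  locally translational and the scene planar; it converges to the projective
  ground truth on phantoms but would average over parallax on strongly
  non-planar real anatomy.
* The bright-blob OD detector assumes the disc is the brightest compact
  structure; bright artifacts or pathology defeat it (the detector interface
  exists precisely so a learned model can replace it).
* The numpy engine is single-threaded BLAS-bound and float64; it is sized
  for desk-scale experiments, not 512-px production training.
* MS-SSIM at 64–128 px uses 3–4 scales, so reported MS-SSIM values are not
  numerically comparable to 5-scale values on 512-px images.
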
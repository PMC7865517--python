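# Methods

This note records the models implemented in `focusfuse`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical conventions — in enough detail to reproduce
or audit any number the package computes.

## Data model

A focal stack is exactly seven single-channel planes of identical size,
ordered by strictly increasing focal distance. On disk planes are 8-bit
(multi-page TIFF or a directory of PNG/TIFF files named
`<stack_id>_fp<k>`); both 0-based (`fp0..fp6`) and 1-based (`fp1..fp7`)
labels are accepted on read, and 0-based indices are used everywhere
internally. In memory every image is a float array on [0, 1];
quantization to disk is round-half-up (`floor(255x + 0.5)`), chosen for
determinism, and out-of-range values raise rather than clip silently —
a wrong normalization upstream should fail loudly. The 8-bit scale
reappears only inside RMSE/PSNR, where the peak value 255 is part of
the metric's definition.

Planes are assumed co-registered for the pyramid and U-Net engines (the
instrument images all seven planes within a fraction of the frame
interval); the ECC engine exists precisely to handle residual drift and
makes no such assumption.

## Laplacian-pyramid fusion

Gaussian levels are built by separable convolution with the 5-tap
binomial kernel h = [1,4,6,4,1]/16 (reflect borders) and factor-2
decimation with ceil semantics, so every resolution — including odd
intermediate sizes such as 720 → 45 → 23 — is supported at any depth.
Bands are `b_k = I_k − E[I_{k+1}]`; the expand operator zero-interleaves
and convolves with 2h. Border handling for expand is applied at the
coarse-sample level (symmetric padding before interleaving), which
makes constants exact fixed points of expand at every size; interior
samples are identical to the textbook zero-stuff-then-filter form.
Because each band stores exactly the difference against the expanded
next level, reconstruction is exact to float rounding for any image,
any level count, and any kernel — the test suite asserts ≤ 1e-6 at
sizes 64–720 and 2–5 levels.

Fusion builds one pyramid per plane and combines coefficients per band
position. The default rule is **salience-weighted combination**:
weights ∝ (local energy)^γ with local energy the 5×5 mean of b², γ = 4,
and the residual combined by plain mean. The rationale: any hard
per-coefficient selection keeps one plane's full noise draw in every
band (and max-|b| actively selects the largest of seven draws), so in
flat image regions — where the planes differ only by sensor noise —
hard selection yields a *noisier* output than the best single plane.
The weighted rule degenerates to an average when activities tie
(suppressing noise by ≈ √7) and to selection when one plane dominates
(an in-focus edge), which is the classic selection/averaging compromise
of the LP-fusion literature. γ trades sharpness against denoising;
γ = 4 keeps edge coefficients within a few percent of pure selection.
Hard `max-local-energy` and `max-abs` rules remain available as
options, as does a `max` residual rule. Default level count is 5, which
fits every supported size down to 64 px (the level count is capped by
the requirement that the deepest Gaussian level be at least 2×2).

## ECC registration and align-and-average fusion

The similarity score is the zero-mean normalized cross-correlation with
population standard deviations; it is symmetric, invariant to positive
affine intensity maps, and undefined (raises) for constant images.
Registration maximizes the enhanced correlation coefficient by the
forward-additive scheme: per iteration the moving image and its
gradients are bilinearly sampled at the warped template coordinates,
steepest-descent images G = ∇I·∂W/∂p are assembled (with their means
removed, matching the zero-mean objective), and the closed-form ECC
increment is applied. Supported motion models: translation, euclidean
(default — a fixed camera exhibits at most drift and slight rotation),
affine, homography. Defaults: eps = 1e-6 on the parameter-update norm,
max 50 iterations, single-scale; an optional coarse-to-fine ladder
(Gaussian pyramid with translations rescaled per level) extends the
capture range to the ±4 px translations exercised in the tests. The
optimizer tracks the best-scoring iterate and never returns a warp
scoring below the initial one; divergence (NaN score or five
consecutive non-improving steps) returns the best-so-far warp flagged
`converged=False`.

Fusion registers the six non-reference planes to the reference (default
index 3, the middle plane), resamples them bilinearly, and averages per
pixel, counting only in-bounds contributions where a warp pushes a
plane off the frame. A constant plane cannot be registered and is
averaged unregistered with a logged warning. Averaging defocused planes
necessarily fades contours — the evaluation reproduces this as lower
gradient energy than the pyramid output on the same stacks — but it is
robust and fully photometric-free.

## U-Net fusion

The network is the standard encoder–decoder with skip connections,
adapted to stack fusion: 7 input channels (planes in focal order — the
channel order is part of the weights contract), 4 encoder groups of two
3×3 conv+ReLU layers and a 2×2 stride-2 max-pool, widths 64/128/256/512
at base width 64; a bottleneck of two 1024-filter convs with dropout
0.5 between them; 4 decoder groups of a learned 2×2 transposed
convolution, skip concatenation, and two 3×3 conv+ReLU layers; and a
1×1 linear output head clamped to [0, 1] at inference. All 3×3
convolutions pad to preserve spatial size — the stated shape contract
(640 in → 40×40×1024 bottleneck → 640 out) forces 'same' padding — so
any square input divisible by 16 works and the parameter count is
independent of the input side. Counting layers by group structure gives
18 conv+ReLU layers (4·2 + 2 + 4·2) plus 4 pools, 4 up-convs and the
output layer; some published descriptions of this architecture count 20
conv+ReLU layers, which the literal group description does not yield —
`layer_census` reports the constructed graph's counts.

Layers and backprop are implemented directly on NumPy (im2col + GEMM
convolutions, slice-accumulated col2im, argmax-routed pooling,
einsum-based transposed convolutions) and verified against numerical
differentiation. Training uses Adam (lr 1e-3, batch 4) on MSE, an 80/20
train/held-out split drawn from the config seed, per-epoch train and
held-out MSE logging, and best-held-out checkpointing; runs are
bit-identical for a fixed seed. Targets are LP-fused images — the
supervision a laboratory can actually produce at scale, since real
stacks have no all-in-focus ground truth.

Training runs in the test suite use the same topology at base width 8
(widths 8/16/32/64/128) on 64-px stacks: the fusion task is spatially
local, so a narrow network already reaches held-out SSIM ≈ 0.97 against
LP targets within ~2 CPU-minutes for 200 stacks × 30 epochs, and the
narrow width keeps the whole suite fast on a single core. The
full-width network is constructed and shape-checked in the tests but
not trained there. Because the network is fully convolutional, the
64-px-trained model applies directly to 128-px stacks; with the
generator's resolution-scaled optics this is how the
higher-resolution-scores-better trend is measured.

## Similarity metrics

All six metrics operate on [0, 1] images of identical shape.

- RMSE and PSNR are computed on the 8-bit scale (difference ×255, peak
  255); PSNR = 20·log₁₀(255/RMSE), +∞ for identical images.
- SAM treats each whole grayscale image as one vector (one component
  per pixel) and returns the angle in radians; a per-pixel 7-band
  variant (`sam_stack`) is available for stack-level diagnostics.
- UQI is the global universal quality index
  4σxyμxμy/((σx²+σy²)(μx²+μy²)) with population statistics, as written;
  a sliding-window variant is available.
- SSIM uses the additive constants C1 = 0.01 and C2 = 0.03 *literally*
  on the [0, 1] scale. This is a deliberate divergence from the
  K-factor parameterization (where C = (K·L)²): the constants here are
  two orders of magnitude larger than K1 = 0.01 squared would give, so
  absolute SSIM values are more forgiving than in the original
  parameterization — comparisons within this package are consistent,
  but values are not directly comparable to SSIM numbers computed with
  the conventional constants. Evaluation runs in an 11×11 Gaussian
  window (σ = 1.5), averaged over the interior with a 5-px border
  excluded; images smaller than the window fall back to global
  statistics with a logged notice. The windowed implementation is
  cross-checked in the tests against scikit-image's SSIM under the
  equivalent K parameterization (agreement to 1e-9).
- MS-SSIM averages the contrast/structure term per scale with 2×2 mean
  decimation between scales, applies luminance at the coarsest scale,
  and uses the standard published exponents renormalized to the number
  of scales used (default 5, needing ≥ 176-px images; requesting too
  many scales raises with the feasible maximum). With one scale it
  reduces exactly to SSIM. Negative per-scale means are floored at 0
  before exponentiation.

`similarity_report` computes all six, mapping any per-metric degeneracy
(constant images, zero vectors) to a null field with the reason
recorded rather than failing the whole report.

## Synthetic stacks

The generator emulates the statistical structure of early-stage embryo
stacks rather than their photorealistic appearance: 1, 2, 4 or 8
translucent cells (alpha 0.6) as anti-aliased discs with a bright
membrane ring, a darker band-limited interior texture and a faint halo,
partially overlapping, composited back-to-front over a vignetted
background. Each cell has an optical depth in [0, 1]; stacks are imaged
at 7 equispaced focus depths. Defocus is per-cell Gaussian blur with
σ = σ_max·|depth − focus|, the simplest model with an analytic
sharpness oracle; σ_max defaults to side/16 (4 px at 64 px), scaling
the optics with resolution. Blur is applied to the *premultiplied*
layer (color×alpha), not to color and alpha separately — over a locally
uniform backdrop the defocused composite then equals the defocus of the
sharp composite, which is what makes the σ-law measurable on a rim
profile (the tests fit it to ~1–2%). Additive Gaussian sensor noise
(σ = 0.01 on [0, 1]) is applied after compositing; the zero-blur,
pre-noise render is kept as ground truth, along with a per-pixel
dominant-depth map (background at depth 0.5).

Scene geometry is validated (≥ 2-px frame margin, at least two distinct
depths whenever there are ≥ 2 cells — otherwise fusion is trivial), and
everything is keyed to explicit seeds: the same arguments reproduce the
same bytes. `make_dataset` cycles cell counts in fixed proportion,
computes each stack's LP-fused target with the default configuration,
and splits 80/20 by a seeded permutation (n = 10 → exactly 8/2).

What passing tests on this generator do **not** show: robustness to
fragmentation debris, uneven illumination beyond a smooth vignette,
optical aberrations other than isotropic Gaussian defocus, occlusion by
opaque material, or the texture statistics of real cytoplasm. Results
on real stacks can be worse in all of these respects; the generator's
role is to make the *relative* claims (fusion beats single planes, the
network can mimic the LP reference, registration recovers known warps)
checkable without restricted clinical data.

## Evaluation protocol

The evaluation grid runs the requested engines on byte-identical stacks
(checksummed per stack) over resolutions × cell counts, with two
references per comparison: the LP-fused image — the protocol available
on real data, where the learned fusion is judged against the pyramid
reference — and the synthetic ground truth, which only simulation
affords. Summaries report the per-cell mean of each metric with a
Student-t 95% confidence half-width (the CI construction is a package
choice); per-stack rows are the source of truth and the summary is
recomputable from them. Desk-scale defaults (64–128 px, 5 stacks per
cell) keep a full run in CPU-minutes; 480–720 px grids are accepted.
Wall-clock timing is measured by a separate harness that records
machine metadata and is labeled informational — timings depend on the
host and are never used as a quality gate.

## Known limitations

- The ECC engine's single-scale capture range is a few pixels; the
  coarse-to-fine ladder extends it, but large rotations combined with
  large translations may still need a better initial warp.
- The NumPy network trains comfortably at 64–128 px and narrow widths;
  full-width 640-px training is out of scope for this implementation
  (construction and inference at 640 are supported and tested).
- SSIM/UQI values are tied to this package's parameterization (see
  above) and should not be compared numerically against
  differently-parameterized implementations.
- The defocus model ignores depth variation *within* a cell; each cell
  blurs rigidly with its scalar depth.
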
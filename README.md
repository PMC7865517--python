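# focusfuse

Multi-focus fusion of 7-plane microscopy focal stacks into a single
all-in-focus image.

Time-lapse embryo incubators image each embryo at seven focal planes
(fd1 < … < fd7) every few minutes; a fully loaded instrument produces
on the order of 10⁵ focal stacks per IVF cycle (84 embryos × 120 h ×
60 / 5-min interval ≈ 1.2·10⁵ acquisitions). Because blastomeres
cleave in 3-D, no single plane resolves every cell — an embryologist
must otherwise inspect all seven images per time point. Fusing each
stack to one image cuts the data an embryologist (or a downstream cell
counter) must handle by a factor of 7 while keeping each cell's sharp
boundary from the plane that resolved it.

`focusfuse` provides three interchangeable fusion engines behind a
common API, plus the measurement and simulation tooling to compare
them:

- **Laplacian-pyramid fusion** (`fuse_lp_stack`): each plane is
  decomposed into band-pass levels `b_k = I_k − E[I_{k+1}]` over a
  Gaussian pyramid (5-tap binomial kernel, exact inverse transform);
  at every band position the seven coefficients are combined with
  weights proportional to a power of their local energy — selection
  where one plane is decisively sharper, averaging (hence denoising)
  where they tie — and the fused pyramid is collapsed back.
- **ECC align-and-average** (`fuse_ecc`): every plane is registered to
  a reference plane by maximizing the enhanced correlation coefficient
  (the zero-mean normalized cross-correlation
  `ZNCC = (1/NM) Σ (I₁−μ₁)(I₂−μ₂) / (σ₁σ₂)`) with a gradient-based,
  sub-pixel-accurate iteration, then the aligned planes are averaged
  per pixel.
- **U-Net fusion** (`build_unet` / `train_unet` / `fuse_unet`): a
  fully convolutional encoder–decoder with skip connections takes the
  seven planes channel-wise (640×640×7 input → 40×40×1024 bottleneck →
  640×640×1 output in the reference configuration) and is trained by
  Adam on a mean-squared-error loss against LP-fused targets. The
  network library (convolutions, pooling, transposed convolutions,
  dropout, backprop, Adam) is implemented natively on NumPy and is
  bit-reproducible given a seed.

Two further modules make the pipeline measurable and testable:

- **Six-metric similarity suite** (`similarity_report`): RMSE, spectral
  angle (SAM), PSNR (8-bit peak), universal quality index (UQI),
  SSIM (11×11 Gaussian window, constants C1 = 0.01, C2 = 0.03 on the
  [0, 1] scale), and multi-scale SSIM.
- **Synthetic stack generator** (`random_scene` / `render_stack` /
  `make_dataset`): embryo-like scenes of 1–8 translucent cells at
  distinct depths, imaged at 7 focus depths with per-cell Gaussian
  defocus `σ = σ_max·|depth − focus|` and sensor noise — with the
  zero-blur render retained as ground truth, which no real recording
  can provide.

## Worked example

```sh
python examples/train_unet.py
```

trains a narrow U-Net (base width 8) on 32 synthetic 64-px stacks for
10 epochs and scores the 8 held-out stacks:

```
epochs run      : 10
final train MSE : 0.003956
best held-out   : 0.003835 (epoch 9)
held-out SSIM vs LP targets: mean 0.943, min 0.921 over 8 stacks
```

The held-out SSIM close to 1 means the learned fusion already
reproduces the Laplacian-pyramid reference it was trained against; a
full run (200 stacks, 30 epochs, `examples/`-scale hardware) reaches
≈ 0.97. The other examples each demonstrate one capability:
`simulate_stacks.py` (generator anatomy and the defocus law),
`fuse_pyramid.py` (fusion beating every single plane's RMSE to ground
truth), `register_ecc.py` (sub-pixel warp recovery),
`score_metrics.py` (the six-metric report), and
`evaluate_methods.py` (the grid comparison with confidence intervals).

A thin CLI wraps the same calls:

```sh
focusfuse simulate --n 20 --size 64 --seed 7 data/
focusfuse fuse --method lp data/syn0000_c1.tiff fused.png
focusfuse metrics fused.png data/syn0000_c1_gt.png
focusfuse train data/ run/ && focusfuse fuse --method unet --weights run/best.npz data/syn0000_c1.tiff fused_unet.png
focusfuse evaluate --weights run/best.npz results/
```

## Layout

```
src/focusfuse/   stackio, pyramid, ecc, nn, unet, metrics, synthetic,
                 evaluation, capacity, cli
examples/        one short narrative script per capability
tests/           pytest suite (unit, property, acceptance)
scripts/         acceptance.py
docs/methods.md  models, assumptions, parameter choices, limitations
```
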
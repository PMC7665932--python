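# Methods

## Problem and model

Magnitude MR images carry Rician-distributed noise: the complex k-space
signal picks up independent zero-mean Gaussian noise in both quadratures,
and taking the magnitude maps a true intensity `A` to
`sqrt((A + n1)^2 + n2^2)` with `n1, n2 ~ N(0, σ²)`. At zero signal this is
a Rayleigh distribution (mean `σ√(π/2)`, variance `(2 − π/2)σ²`); at high
SNR it approaches additive Gaussian noise plus a `σ²/2A` bias. Noise
levels are quoted as a percentage of the peak clean intensity:
"p % noise" means `σ = p/100` on the internal [0, 1] scale. This is the
package's one convention choice for an otherwise loosely used term; it
matches common MR-denoising benchmark practice.

The denoiser is a fully convolutional residual network:

1. **Multifeature extraction.** Three parallel same-padded convolutions
   with kernel sizes 3×3, 5×5, 7×7 and counts 12, 20, 32 scan the input
   with their centers aligned; the 64 resulting feature maps are
   concatenated and passed through PReLU. The mixed receptive fields give
   the first layer multiscale perception of shallow structure. All
   convolutions use unit stride and zero padding so every layer preserves
   the spatial size — a hard requirement of the global skip subtraction
   (a strided first layer would shrink the map and make the final
   subtraction ill-defined, which is why the package is strictly
   same-size end to end).
2. **Residual-unit chain.** `n` identical units of
   `Conv(3×3, 64) → BN → PReLU → Conv(3×3, 64) → BN`, added to the unit
   input through an identity shortcut and finished with PReLU. The
   internal layout is the standard two-convolution residual block; batch
   normalization stabilizes the activation distribution against internal
   covariate shift, and the shortcuts keep gradients alive through depth.
3. **Reconstruction and global skip.** A final 3×3 convolution maps the
   features to the *noise residual* `R(y)`; the output image is
   `y − R(y)`. Learning the residual rather than the clean image is the
   key trick: near convergence the target mapping is close to zero rather
   than close to the identity, which deep stacks optimize far more easily.

With the default 6 residual units the network has
1 + 6×2 + 1 = 14 weight-carrying layers; counting the input mapping stage
once more gives the conventional "15-layer" description. Depth and widths
are configurable through `ModelSpec`, which asserts that the first-layer
kernel counts sum to the chain width.

## Losses

* **Pixel loss** — mean over the batch of the per-sample squared 2-norm
  `(1/N) Σ ‖(x − F(x)) − y‖₂²` between the denoised output and the clean
  label. A per-pixel reduction is available as an option.
* **Perceptual loss** — the same distance computed on feature maps
  `φ_i(·)` of a *frozen* extractor, comparing images at a semantic level;
  `φ` is the activation after the i-th convolution of the loss network.
* **Joint loss** — `L = L_pixel + λ·L_perceptual`. λ defaults to 0.01 so
  the perceptual term refines rather than dominates; the value is a
  package choice (no canonical value exists) and is configurable.

The default extractor is a small frozen random CNN (3 same-padded 3×3
convolution stages, 8 channels, PReLU, fixed seed): random convolutional
features are a legitimate, fully deterministic feature space for
perceptual distances and keep the package self-contained. A
`pretrained-vgg` registry slot exists for the classical pretrained-VGG
perceptual loss; it requires the optional torchvision integration with
downloaded weights and raises a clear error otherwise. Extractor
parameters never receive gradient updates; the backward path through the
extractor propagates only the input gradient.

## Training

Training samples random paired crops (default 45×45) from the
(noisy, clean) pairs, shuffles them into minibatches with a seeded
permutation each epoch, and optimizes with bias-corrected Adam
(`τ₁ = 0.9`, `τ₂ = 0.999`, `ε = 1e-8`) or plain SGD under a step-halving
schedule `lr(t) = lr₀ · 0.5^⌊t/T⌋` (full-scale `T = 2×10⁵`). Default
rates are 1e-4 for Adam and 0.01 for SGD — each printed rate mapped to
the optimizer it is plausible with, since 0.01 under Adam routinely
diverges. Default batch sizes are 64 for the pixel loss and 16 for the
joint loss. The optimizer steps on the *per-pixel-normalized* loss: the
same minimizer as the per-sample sum, but gradient magnitudes become
independent of the patch area, so the quoted SGD rate is usable at any
crop size (Adam is nearly invariant to this scaling). If the loss or a
gradient goes non-finite, training aborts and restores the parameters of
the last completed epoch.

Weight initialization is a seeded fan-in-scaled Gaussian except the
reconstruction layer, which starts at zero: the untrained network is then
*exactly* the identity map (residual ≡ 0, denoised == noisy), the natural
origin for residual denoising, and short desk-scale runs descend from the
noisy baseline instead of from random distortion. PReLU slopes start at
0.25 per channel; BN uses `ε = 1e-5` and running-statistic momentum 0.9.
Training is a pure function of (initial parameters, dataset, config,
seed).

## Synthetic data

The phantom generator composes soft-edged ellipses and annuli (sigmoid
radial profiles, alpha-composited) of varying intensity on a 0.05
background, mimicking the gross geometry of brain MR slices — a skull
rim, tissue blobs — with intensities guaranteed in [0, 1]. It emulates
the *piecewise-smooth, structured* character of MR slices that a denoiser
must preserve; it does not emulate anatomy, partial-volume texture,
acquisition artifacts, bias fields, or spatially correlated noise.
Passing tests therefore demonstrate the mechanics of the method (residual
learning, noise statistics, metric behavior) rather than clinical
denoising performance, which requires real MR data (e.g. glioblastoma
imaging studies) and full-scale training. Noisy images are deliberately *not* clipped to
[0, 1] in memory — clipping would bias the noise distribution the network
sees; clipping happens only at 8/16-bit image export.

## Patch bookkeeping

Grid extraction anchors at offset 0 and keeps only full patches, so a
`d`-pixel axis yields `⌊(d − p)/s⌋ + 1` blocks. The standard
dataset-statistics setting (32×32 blocks, stride 10) gives 15×19 = 285
blocks per 180×215 slice and 85,500 over a 300-image training set — the
conventional "about 86,000" training-block count (unaugmented). Random
45×45 crops are the training-time sampler; both schemes are provided
because both are standard. Augmentation adds the three mirror images
and/or seeded cyclic translations, always applying the identical
transform to both members of a pair.

## Metrics

PSNR and SSIM are computed on the 0–255 scale (internal [0, 1] values are
multiplied by 255; 16-bit data is rescaled before the metric, so the
printed 255² peak applies uniformly). `PSNR = 10·log₁₀(255²/MSE)` with an
explicit `inf` flag for identical images. SSIM is the product of
luminance, contrast and structure factors computed from *global* image
statistics with population (1/MN) estimators and the conventional
stabilizers `C₁ = (0.01·255)²`, `C₂ = (0.03·255)²`, `C₃ = C₂/2`. The
11×11 Gaussian sliding-window variant (scikit-image) is available behind
`windowed=True` for cross-tool comparison. Global-statistics SSIM is 1
exactly iff the images are identical (the equality case is returned
exactly to avoid 1-ulp square-root round-off) and can be negative for
anticorrelated images; raw values are reported unclamped even though the
index is often described as ranging over [0, 1].

## Desk-scale study conditions

CPU-scale runs use a *tiny* model — the same three first-layer kernel
sizes with counts (3, 5, 8), 16-channel chain, 3 residual units — trained
with Adam for 200 iterations on 8 phantoms of 64×64 at a given noise
level, batch 8, 32×32 crops, lr 1e-3 halved every 100 iterations (the
full-scale schedule compressed proportionally to the 200-step budget; at
the full-scale 1e-4 a 200-step run barely moves the parameters).
Held-out evaluation uses 16 fresh phantoms. Under these conditions the
trained model at 7% Rician noise gains ~8 dB mean PSNR over the noisy
baseline.

The noise-level sweep follows the noise-specific protocol standard for
this family of denoisers: one model is trained per noise intensity
(1, 4, 7, 10, 13 %) and each is evaluated at its own level. This is what
produces the characteristic monotone SSIM-versus-noise table. A single
fixed-level model applied across foreign levels does not reproduce the
monotone trend at the low-noise end: it learns the background bias of its
training noise and over-corrects nearly-clean inputs, a known limitation
of noise-specific models (noise-blind operation would require training
over a noise-level range, which is out of scope here).

## Numerical choices and edge cases

* Convolutions are im2col + BLAS matrix products in float64; gradients
  for every layer are hand-derived and verified against central finite
  differences (relative error < 1e-4 on small tensors, typically ~1e-8).
* BN train mode requires ≥ 2 samples per channel and uses
  `σ = sqrt(var + ε)`; eval mode uses running statistics.
* `percent = 0` noise returns the clean image bit-exactly.
* The residual returned by `forward` is recomputed as `noisy − denoised`
  so the skip-connection identity holds bit-exactly in floating point.
* Images smaller than the largest first-layer kernel (7×7) are rejected;
  grid extraction on an image smaller than the patch returns an empty
  set (not an error).
* All randomness flows through `numpy.random.Generator` objects seeded
  from explicit integers; per-image seeds are spawned from a single
  `SeedSequence`, so datasets and training runs are pure functions of
  their seed.

## Known limitations

* Phantoms are not anatomy; results quantify the method's mechanics, not
  clinical denoising quality.
* The spatial noise field is i.i.d. per pixel; real parallel-imaging
  reconstructions have spatially varying, correlated noise.
* The perceptual loss defaults to random (not pretrained) features;
  pretrained-VGG behavior is not exercised in the offline test suite.
* Training is single-device, full-precision, with no early stopping
  beyond the divergence abort.
* Desk-scale budgets (200 iterations, 16-channel model) are two to three
  orders of magnitude below a full training run; absolute PSNR/SSIM
  values are correspondingly below published full-scale figures.
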
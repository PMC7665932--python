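# mrdenoise

Denoising of magnitude MR images with a multifeature-extraction deep
residual network, plus everything needed to study it end to end without
real patient data: an MR-like phantom generator, a Rician noise
simulator, patch pipelines, pixel/perceptual/joint losses, Adam/SGD
training, and PSNR/SSIM evaluation.

## The problem and the model

Magnitude MR images are corrupted by Rician noise: the complex signal
acquires independent Gaussian noise in both quadratures, so a noise-free
intensity A is observed as `sqrt((A + n1)² + n2²)`, `n1, n2 ~ N(0, σ²)`.
"p % noise" means σ = p/100 of the peak intensity. Rician noise is
signal-dependent — Rayleigh-distributed on dark background, approximately
Gaussian on bright tissue — which makes it harder to remove than additive
noise, especially at high intensity levels.

The denoiser learns the **noise residual** rather than the clean image.
With noisy input y, the network predicts R(y) ≈ v (the noise) and returns

    x̂ = y − R(y)                       (global skip connection)

Its architecture:

* a **multifeature extraction layer**: three parallel same-padded
  convolutions (12×3×3, 20×5×5, 32×7×7 kernels, centers aligned)
  concatenated to 64 channels and passed through PReLU, giving the first
  layer multiscale perception;
* a chain of **residual units** `Conv(3×3,64) → BN → PReLU →
  Conv(3×3,64) → BN` with identity shortcuts, then PReLU;
* a 3×3 **reconstruction layer** producing the residual image.

Training minimizes the pixel loss `(1/N) Σ ‖(y − R(y)) − x‖₂²`, optionally
combined with a perceptual term computed in the feature space of a frozen
extractor network: `L = L_pixel + λ·L_perc`. Optimization uses
bias-corrected Adam (τ₁ = 0.9, τ₂ = 0.999) or SGD with a step-halving
learning-rate schedule. Quality is reported as `PSNR = 10·log₁₀(255²/MSE)`
and the global-statistics SSIM `l·c·s`. See `docs/methods.md` for the
full account.

## Worked example

```python
import numpy as np
from mrdenoise import (ResidualDenoiser, NoiseSpec, make_dataset, psnr, ssim)

pairs = make_dataset(8, 64, 64, NoiseSpec(model="rician", percent=7.0), seed=1)
test  = make_dataset(4, 64, 64, NoiseSpec(model="rician", percent=7.0), seed=99)

est = ResidualDenoiser(
    kernel_plan=((3, 3), (5, 5), (7, 8)), unit_width=16, n_residual_units=3,
    learning_rate=1e-3, batch_size=8, epochs=10, max_iterations=200,
    lr_halving_period=100.0, crop_size=32, crops_per_image=20, random_state=1,
)
est.fit([p.noisy for p in pairs], [p.clean for p in pairs])

noisy_psnr = np.mean([psnr(p.clean, p.noisy) for p in test])
print(f"noisy baseline : {noisy_psnr:.2f} dB")
print(f"denoised       : {est.score([p.noisy for p in test], [p.clean for p in test]):.2f} dB")
print(f"epoch loss     : {est.history_.epoch_loss[0]:.4f} -> {est.history_.epoch_loss[-1]:.4f}")
```

prints

```
noisy baseline : 23.15 dB
denoised       : 31.26 dB
epoch loss     : 0.0051 -> 0.0008
```

i.e. 200 Adam iterations of the 16-channel desk-scale model already gain
≈ 8 dB over the 7 % Rician noisy baseline on held-out phantoms, with the
per-pixel training loss falling by ~6×. The same pipeline is scriptable
from the shell:

```bash
mrdenoise simulate --n 8 --size 64x64 --noise rician:7 --seed 1 --out data/
mrdenoise train    --data data/ --tiny --seed 1 --out run/
mrdenoise denoise  --checkpoint run/checkpoint.npz --input data/img000_noisy.png --out out/
mrdenoise eval     --checkpoint run/checkpoint.npz --data data/ --percents 1,4,7,10,13 --out report
```

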
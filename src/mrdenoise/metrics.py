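"""PSNR and SSIM image-quality metrics and noise-level sweep reports.

Both metrics compare a reference image ``f`` with a test image ``d`` on
the 8-bit 0-255 scale (inputs on the internal [0, 1] scale are multiplied
by 255 internally):

* ``PSNR = 10 log10(255^2 / MSE)`` with ``MSE`` the per-pixel mean squared
  difference; identical images give infinite PSNR, reported as ``inf``.
* ``SSIM = l * c * s`` computed from *global* image statistics — means
  ``mu``, population standard deviations ``sigma`` (1/MN normalization),
  and covariance ``sigma_fd`` — with the conventional stabilizers
  ``C1 = (0.01 L)^2``, ``C2 = (0.03 L)^2``, ``C3 = C2 / 2`` for dynamic
  range ``L = 255``.  SSIM is 1 exactly iff the images are identical, and
  can be negative for anticorrelated images; raw values are reported
  unclamped.  The common 11x11 Gaussian sliding-window SSIM variant is
  available with ``windowed=True`` for cross-tool comparison.

``evaluate_sweep`` corrupts a clean test set at each requested noise
percent, denoises with a given model, and tabulates mean PSNR/SSIM per
noise level — the standard layout for comparing denoisers across noise
intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phantom import NoiseSpec, add_noise

__all__ = [
    "SSIMConstants",
    "MetricsReport",
    "mse_metric",
    "psnr",
    "ssim",
    "evaluate_sweep",
]

_L = 255.0


@dataclass(frozen=True)
class SSIMConstants:
    """Stabilizers guarding the SSIM denominators, on the 0-255 scale."""

    C1: float = (0.01 * _L) ** 2
    C2: float = (0.03 * _L) ** 2
    C3: float = (0.03 * _L) ** 2 / 2.0

    def __post_init__(self) -> None:
        if self.C1 <= 0 or self.C2 <= 0 or self.C3 <= 0:
            raise ValueError("SSIM constants must be positive")


def _pair_255(f: np.ndarray, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    f = np.asarray(f, dtype=np.float64)
    d = np.asarray(d, dtype=np.float64)
    if f.shape != d.shape:
        raise ValueError(f"image dimensions differ: {f.shape} vs {d.shape}")
    if f.ndim != 2:
        raise ValueError(f"expected 2-D images, got shape {f.shape}")
    return f * _L, d * _L


def mse_metric(f: np.ndarray, d: np.ndarray) -> float:
    """Mean squared pixel difference on the 0-255 scale."""
    f255, d255 = _pair_255(f, d)
    return float(np.mean((f255 - d255) ** 2))


def psnr(f: np.ndarray, d: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images."""
    mse = mse_metric(f, d)
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(_L**2 / mse))


def ssim(
    f: np.ndarray,
    d: np.ndarray,
    constants: SSIMConstants | None = None,
    windowed: bool = False,
) -> float:
    """Structural similarity from global image statistics.

    The luminance, contrast and structure factors are
    ``l = (2 mu_f mu_d + C1) / (mu_f^2 + mu_d^2 + C1)``,
    ``c = (2 sigma_f sigma_d + C2) / (sigma_f^2 + sigma_d^2 + C2)``,
    ``s = (sigma_fd + C3) / (sigma_f sigma_d + C3)``.
    ``windowed=True`` instead delegates to scikit-image's sliding-window
    implementation.
    """
    if constants is None:
        constants = SSIMConstants()
    f255, d255 = _pair_255(f, d)
    if np.array_equal(f255, d255):
        return 1.0  # exact by definition; avoids 1-ulp sqrt round-off
    if windowed:
        from skimage.metrics import structural_similarity

        return float(structural_similarity(f255, d255, data_range=_L))
    mu_f, mu_d = f255.mean(), d255.mean()
    # population (1/MN) estimators
    sig_f, sig_d = f255.std(), d255.std()
    cov = float(np.mean((f255 - mu_f) * (d255 - mu_d)))
    l = (2 * mu_f * mu_d + constants.C1) / (mu_f**2 + mu_d**2 + constants.C1)
    c = (2 * sig_f * sig_d + constants.C2) / (sig_f**2 + sig_d**2 + constants.C2)
    s = (cov + constants.C3) / (sig_f * sig_d + constants.C3)
    return float(l * c * s)


@dataclass
class MetricsReport:
    """Mean PSNR/SSIM per noise percent for one method label."""

    method: str = "proposed"
    noise_percents: list = field(default_factory=list)
    mean_psnr: list = field(default_factory=list)
    mean_ssim: list = field(default_factory=list)
    per_image: dict = field(default_factory=dict)  # percent -> list of (psnr, ssim)

    def row(self, percent: float) -> tuple[float, float]:
        i = self.noise_percents.index(percent)
        return self.mean_psnr[i], self.mean_ssim[i]

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "rows": [
                {"noise_percent": p, "mean_psnr": ps, "mean_ssim": ss}
                for p, ps, ss in zip(self.noise_percents, self.mean_psnr, self.mean_ssim)
            ],
        }

    def to_csv(self) -> str:
        lines = ["noise_percent,method,mean_psnr,mean_ssim"]
        for p, ps, ss in zip(self.noise_percents, self.mean_psnr, self.mean_ssim):
            lines.append(f"{p},{self.method},{ps},{ss}")
        return "\n".join(lines) + "\n"


def evaluate_sweep(
    model,
    clean_images: list[np.ndarray],
    noise_percents: list[float],
    noise_model: str = "rician",
    seed: int = 0,
    method: str = "proposed",
) -> MetricsReport:
    """Corrupt, denoise, and score a test set at several noise levels.

    ``model`` is anything with a ``denoise(image) -> image`` method (a
    :class:`~mrdenoise.network.DenoisingNetwork` or estimator).  Rows are
    sorted by noise percent; means are arithmetic over the test set.
    Infinite per-image PSNR (possible at 0% noise) propagates to an
    infinite mean, flagged as ``inf``.
    """
    if not clean_images:
        raise ValueError("test set is empty")
    report = MetricsReport(method=method)
    ss = np.random.SeedSequence(seed)
    for percent in sorted(noise_percents):
        scores = []
        for img, child in zip(clean_images, ss.spawn(len(clean_images))):
            nspec = NoiseSpec(
                model=noise_model,
                percent=percent,
                seed=int(child.generate_state(1)[0] % (2**31)),
            )
            pair = add_noise(img, nspec)
            denoised = model.denoise(pair.noisy)
            scores.append((psnr(img, denoised), ssim(img, denoised)))
        report.noise_percents.append(percent)
        report.mean_psnr.append(float(np.mean([s[0] for s in scores])))
        report.mean_ssim.append(float(np.mean([s[1] for s in scores])))
        report.per_image[percent] = scores
    return report
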
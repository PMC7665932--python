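"""Synthetic MR-like phantom images and Rician/Gaussian noise simulation.

Magnitude MR images carry Rician-distributed noise: the acquired complex
signal has independent zero-mean Gaussian noise in its real and imaginary
channels, and taking the magnitude turns a noise-free intensity ``A`` into

    A_noisy = sqrt((A + n1)^2 + n2^2),    n1, n2 ~ N(0, sigma^2).

At zero signal this reduces to a Rayleigh distribution (mean ``sigma *
sqrt(pi/2)``, variance ``(2 - pi/2) * sigma^2``); at high SNR it approaches
additive Gaussian noise of the same sigma.  Noise levels are quoted as a
percentage of the peak intensity of the clean range: "p% noise" means
``sigma = p/100`` on the internal [0, 1] scale.

The phantom generator produces smooth-edged elliptical and annular
structures on a low-intensity background, mimicking the gross geometry of
brain MR slices (skull rim, tissue blobs) for training and testing the
denoiser without any real patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "NoiseSpec",
    "ImagePair",
    "validate_image",
    "generate_phantom",
    "add_noise",
    "make_dataset",
]

_NOISE_MODELS = ("rician", "gaussian")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model and level.

    Parameters
    ----------
    model : {"rician", "gaussian"}
        Noise distribution.  Rician is the physical model for magnitude MR
        images; Gaussian is its high-SNR limit.
    percent : float
        Noise standard deviation as a percentage of the peak clean
        intensity (1.0 on the internal scale), so ``sigma = percent / 100``.
    seed : int
        Seed for the noise realization.
    """

    model: str = "rician"
    percent: float = 7.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in _NOISE_MODELS:
            raise ValueError(
                f"unknown noise model {self.model!r}; expected one of {_NOISE_MODELS}"
            )
        if self.percent < 0:
            raise ValueError(f"noise percent must be >= 0, got {self.percent}")

    @property
    def sigma(self) -> float:
        """Noise standard deviation on the [0, 1] intensity scale."""
        return self.percent / 100.0


@dataclass
class ImagePair:
    """A clean reference image and its noise-corrupted counterpart.

    ``noisy`` is *not* clipped to [0, 1]: clipping would bias the noise
    distribution the network trains on.  Clipping happens only at image
    export.
    """

    clean: np.ndarray
    noisy: np.ndarray
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def __post_init__(self) -> None:
        if self.clean.shape != self.noisy.shape:
            raise ValueError(
                f"clean and noisy shapes differ: {self.clean.shape} vs {self.noisy.shape}"
            )


def validate_image(img: np.ndarray, name: str = "image") -> np.ndarray:
    """Check a 2-D intensity grid: finite, values in [0, 1]."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"{name} must be 2-D, got shape {img.shape}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError(f"{name} has empty dimension: {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError(f"{name} contains non-finite values")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError(f"{name} intensities outside [0, 1]")
    return img


def generate_phantom(
    height: int, width: int, n_shapes: int = 6, seed: int = 0
) -> np.ndarray:
    """Generate a synthetic MR-like phantom image.

    The image is a smooth low-intensity background with ``n_shapes``
    soft-edged elliptical or annular structures of varying intensity,
    alpha-composited so intensities stay in [0, 1].  Deterministic for a
    fixed seed.

    Parameters
    ----------
    height, width : int
        Image dimensions in pixels, each >= 16.
    n_shapes : int
        Number of structures; 0 gives the bare uniform background.
    seed : int
        RNG seed.

    Returns
    -------
    ndarray of shape (height, width), float64 in [0, 1].
    """
    if height < 16 or width < 16:
        raise ValueError(f"height and width must be >= 16, got {height}x{width}")
    if n_shapes < 0:
        raise ValueError(f"n_shapes must be >= 0, got {n_shapes}")
    rng = np.random.default_rng(seed)

    img = np.full((height, width), 0.05, dtype=np.float64)
    if n_shapes == 0:
        return img

    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    for _ in range(n_shapes):
        cy = rng.uniform(0.15, 0.85) * height
        cx = rng.uniform(0.15, 0.85) * width
        ay = rng.uniform(0.08, 0.35) * height
        ax = rng.uniform(0.08, 0.35) * width
        theta = rng.uniform(0.0, np.pi)
        intensity = rng.uniform(0.2, 0.95)
        softness = rng.uniform(0.05, 0.25)
        annular = rng.random() < 0.3

        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        r2 = (u / ax) ** 2 + (v / ay) ** 2
        # soft ellipse edge: ~1 inside, ~0 outside, sigmoid transition
        alpha = expit((1.0 - r2) / softness)
        if annular:
            alpha = alpha - expit((rng.uniform(0.2, 0.6) - r2) / softness)
        # alpha compositing keeps the result in [0, 1]
        img = img * (1.0 - alpha) + intensity * alpha

    return np.clip(img, 0.0, 1.0)


def add_noise(clean: np.ndarray, spec: NoiseSpec) -> ImagePair:
    """Corrupt a clean image with Rician or Gaussian noise.

    Rician: each pixel ``A`` becomes ``sqrt((A + n1)^2 + n2^2)`` with
    ``n1, n2`` iid ``N(0, sigma^2)``; Gaussian: ``A + n1``.  The output is
    not clipped.  ``percent = 0`` returns the clean image bit-exactly.
    """
    clean = validate_image(clean, "clean")
    sigma = spec.sigma
    if sigma == 0.0:
        return ImagePair(clean=clean, noisy=clean.copy(), noise=spec)

    rng = np.random.default_rng(spec.seed)
    n1 = rng.normal(0.0, sigma, size=clean.shape)
    if spec.model == "rician":
        n2 = rng.normal(0.0, sigma, size=clean.shape)
        noisy = np.sqrt((clean + n1) ** 2 + n2**2)
    else:  # gaussian
        noisy = clean + n1
    return ImagePair(clean=clean, noisy=noisy, noise=spec)


def make_dataset(
    n_images: int,
    height: int = 180,
    width: int = 215,
    spec: NoiseSpec | None = None,
    seed: int = 0,
    n_shapes: int = 6,
) -> list[ImagePair]:
    """Generate ``n_images`` independent phantom/noisy pairs.

    A pure function of its seed: per-image phantom and noise seeds are
    spawned from a single :class:`numpy.random.SeedSequence`, so the same
    call always yields an identical dataset.  Default dimensions follow the
    benchmark convention of 180x215 slices.
    """
    if n_images < 1:
        raise ValueError(f"n_images must be >= 1, got {n_images}")
    if spec is None:
        spec = NoiseSpec()

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_images)
    pairs: list[ImagePair] = []
    for i in range(n_images):
        phantom_seed = int(children[2 * i].generate_state(1)[0] % (2**31))
        noise_seed = int(children[2 * i + 1].generate_state(1)[0] % (2**31))
        clean = generate_phantom(height, width, n_shapes=n_shapes, seed=phantom_seed)
        per_image = NoiseSpec(model=spec.model, percent=spec.percent, seed=noise_seed)
        pairs.append(add_noise(clean, per_image))
    return pairs
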
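"""Pixel-wise, perceptual, and joint training losses.

The pixel loss is the mean over the batch of the per-sample squared
2-norm between the denoised output and the clean label.  The perceptual
loss applies the same distance in the feature space of a fixed (frozen)
extractor network, comparing images at a semantic rather than pixel level;
the joint loss is ``L = L_mse + lambda * L_perceptual``.

Extractors are pluggable through a registry:

``identity``
    Features are the image itself; the perceptual loss then coincides with
    the pixel loss (useful for testing and as a degenerate baseline).
``fixture``
    A small fixed-seed random convolutional network (3 conv stages with
    PReLU), frozen.  Random convolutional features are a standard stand-alone
    choice for feature-space distances when no pretrained classifier is in
    use, and they keep the whole pipeline self-contained and deterministic.
``pretrained-vgg``
    A pretrained VGG classifier stage; requires torchvision and downloaded
    weights, so constructing it raises unless that optional integration is
    available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._layers import Conv2d, PReLU

__all__ = [
    "LossConfig",
    "FeatureExtractor",
    "IdentityExtractor",
    "FixtureExtractor",
    "get_extractor",
    "EXTRACTORS",
    "mse_loss",
    "mse_loss_grad",
    "perceptual_loss",
    "perceptual_loss_grad",
    "joint_loss",
    "joint_loss_grad",
]


def _as_batch(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    if x.ndim == 3:
        x = x[:, None]
    if x.ndim != 4:
        raise ValueError(f"expected image batch, got shape {x.shape}")
    return x


class FeatureExtractor:
    """Base class: a frozen map from images to feature tensors."""

    n_stages: int = 1

    def features(self, x: np.ndarray, layer_index: int) -> np.ndarray:
        raise NotImplementedError

    def features_and_backward(self, x: np.ndarray, layer_index: int):
        """Return (features, vjp) where vjp maps a feature-space gradient
        back to an input-space gradient.  Extractor parameters never
        receive gradients."""
        raise NotImplementedError

    def check_layer(self, layer_index: int) -> None:
        if not 1 <= layer_index <= self.n_stages:
            raise ValueError(
                f"layer_index {layer_index} out of range 1..{self.n_stages}"
            )


class IdentityExtractor(FeatureExtractor):
    """phi = id: reduces the perceptual loss to the pixel loss."""

    n_stages = 1

    def features(self, x: np.ndarray, layer_index: int) -> np.ndarray:
        self.check_layer(layer_index)
        return _as_batch(x)

    def features_and_backward(self, x: np.ndarray, layer_index: int):
        self.check_layer(layer_index)
        return _as_batch(x), lambda g: g


class FixtureExtractor(FeatureExtractor):
    """Small frozen random CNN: 3 same-padded conv stages with PReLU.

    Weights are drawn once from a fixed seed and never updated, so the
    feature map is a deterministic function of the input.  Single-channel
    input is used directly; multi-channel input must match ``in_channels``.
    """

    n_stages = 3

    def __init__(self, in_channels: int = 1, width: int = 8, seed: int = 1234) -> None:
        rng = np.random.default_rng(seed)
        chans = [in_channels] + [width] * self.n_stages
        self.convs = [Conv2d(chans[i], chans[i + 1], 3, rng=rng) for i in range(self.n_stages)]
        self.acts = [PReLU(width, init=0.25) for _ in range(self.n_stages)]

    def features(self, x: np.ndarray, layer_index: int) -> np.ndarray:
        self.check_layer(layer_index)
        h = _as_batch(x)
        for i in range(layer_index):
            h = self.convs[i].forward(h, train=False)
            h = self.acts[i].forward(h, train=False)
        return h

    def features_and_backward(self, x: np.ndarray, layer_index: int):
        self.check_layer(layer_index)
        h = _as_batch(x)
        stages = []
        for i in range(layer_index):
            h = self.convs[i].forward(h, train=True)
            h = self.acts[i].forward(h, train=True)
            stages.append(i)

        def vjp(g: np.ndarray) -> np.ndarray:
            for i in reversed(stages):
                g = self.acts[i].backward(g)
                g = self.convs[i].backward(g)
                # extractor stays frozen: discard its parameter gradients
                self.convs[i].grads["weight"][...] = 0.0
                self.convs[i].grads["bias"][...] = 0.0
                self.acts[i].grads["k"][...] = 0.0
            return g

        return h, vjp


def _vgg_unavailable(**kwargs):
    raise RuntimeError(
        "the 'pretrained-vgg' extractor needs torchvision with downloaded "
        "VGG weights; install the optional integration or use the "
        "'fixture' extractor"
    )


EXTRACTORS = {
    "identity": IdentityExtractor,
    "fixture": FixtureExtractor,
    "pretrained-vgg": _vgg_unavailable,
}

_DEFAULT_LAYER_INDEX = {"identity": 1, "fixture": 2, "pretrained-vgg": 4}


def get_extractor(kind: str, **kwargs) -> FeatureExtractor:
    """Instantiate a registered feature extractor by name."""
    if kind not in EXTRACTORS:
        raise ValueError(f"unknown extractor {kind!r}; known: {sorted(EXTRACTORS)}")
    return EXTRACTORS[kind](**kwargs)


@dataclass
class LossConfig:
    """Joint-loss configuration.

    ``lam`` weights the perceptual term; 0 recovers the pure pixel loss.
    ``layer_index`` selects which extractor stage supplies the features
    (the activation after that convolution); None picks the extractor's
    default stage.
    """

    lam: float = 0.01
    extractor: str = "fixture"
    layer_index: int | None = None
    extractor_seed: int = 1234

    _extractor_obj: FeatureExtractor | None = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lambda must be >= 0, got {self.lam}")
        if self.layer_index is None:
            self.layer_index = _DEFAULT_LAYER_INDEX.get(self.extractor, 1)

    def build_extractor(self) -> FeatureExtractor:
        if self._extractor_obj is None:
            kwargs = {"seed": self.extractor_seed} if self.extractor == "fixture" else {}
            self._extractor_obj = get_extractor(self.extractor, **kwargs)
        return self._extractor_obj


def _check_pair(denoised: np.ndarray, clean: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = _as_batch(denoised)
    y = _as_batch(clean)
    if d.shape != y.shape:
        raise ValueError(f"shape mismatch: denoised {d.shape} vs clean {y.shape}")
    return d, y


def mse_loss(denoised: np.ndarray, clean: np.ndarray, reduction: str = "sum") -> float:
    """Mean over samples of the squared 2-norm of the pixel error.

    ``reduction='sum'`` (default) sums squared differences within each
    sample before averaging over the batch; ``'mean'`` divides further by
    the pixel count, giving a per-pixel MSE.
    """
    d, y = _check_pair(denoised, clean)
    per_sample = ((d - y) ** 2).sum(axis=(1, 2, 3))
    if reduction == "mean":
        per_sample = per_sample / (d.shape[1] * d.shape[2] * d.shape[3])
    elif reduction != "sum":
        raise ValueError(f"unknown reduction {reduction!r}")
    return float(per_sample.mean())


def mse_loss_grad(denoised: np.ndarray, clean: np.ndarray, reduction: str = "sum") -> np.ndarray:
    """Gradient of :func:`mse_loss` w.r.t. the denoised batch."""
    d, y = _check_pair(denoised, clean)
    g = 2.0 * (d - y) / d.shape[0]
    if reduction == "mean":
        g = g / (d.shape[1] * d.shape[2] * d.shape[3])
    return g


def perceptual_loss(
    denoised: np.ndarray, clean: np.ndarray, config: LossConfig | None = None
) -> float:
    """Squared feature-space distance, averaged over the batch."""
    if config is None:
        config = LossConfig()
    d, y = _check_pair(denoised, clean)
    ext = config.build_extractor()
    fd = ext.features(d, config.layer_index)
    fy = ext.features(y, config.layer_index)
    return float(((fd - fy) ** 2).sum(axis=(1, 2, 3)).mean())


def perceptual_loss_grad(
    denoised: np.ndarray, clean: np.ndarray, config: LossConfig | None = None
) -> np.ndarray:
    """Gradient of :func:`perceptual_loss` w.r.t. the denoised batch."""
    if config is None:
        config = LossConfig()
    d, y = _check_pair(denoised, clean)
    ext = config.build_extractor()
    fd, vjp = ext.features_and_backward(d, config.layer_index)
    fy = ext.features(y, config.layer_index)
    return vjp(2.0 * (fd - fy) / d.shape[0])


def joint_loss(
    denoised: np.ndarray, clean: np.ndarray, config: LossConfig | None = None
) -> float:
    """Pixel loss plus ``lam`` times the perceptual loss."""
    if config is None:
        config = LossConfig()
    total = mse_loss(denoised, clean)
    if config.lam > 0:
        total += config.lam * perceptual_loss(denoised, clean, config)
    return total


def joint_loss_grad(
    denoised: np.ndarray, clean: np.ndarray, config: LossConfig | None = None
) -> np.ndarray:
    """Gradient of :func:`joint_loss` w.r.t. the denoised batch."""
    if config is None:
        config = LossConfig()
    g = mse_loss_grad(denoised, clean)
    if config.lam > 0:
        g = g + config.lam * perceptual_loss_grad(denoised, clean, config)
    return g
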
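"""Multifeature-extraction residual denoising network.

Architecture
------------
1. **Multifeature layer** — three parallel same-padded convolutions with
   kernel sizes 3, 5, 7 and counts 12, 20, 32 scan the input with their
   centers aligned; the feature maps are concatenated into 64 channels and
   passed through PReLU.  Mixing receptive-field sizes in the first layer
   gives the network multiscale perception of shallow structure.
2. **Residual-unit chain** — a series of identical units, each
   ``Conv(3x3) -> BN -> PReLU -> Conv(3x3) -> BN``, added to the unit input
   through an identity shortcut and finished with PReLU.  BN keeps the
   per-unit activation distribution stable during training; the shortcuts
   keep gradients flowing through a deep chain.
3. **Reconstruction layer** — a final 3x3 convolution maps the 64-channel
   features to ``c`` output channels: the predicted *noise residual*.
4. **Global skip** — the denoised image is ``noisy - residual``.  Learning
   the residual rather than the clean image is easier for deep nets: near
   the clean solution the target mapping is close to zero, not close to
   identity.

The whole network is fully convolutional with no pooling, so spatial
dimensions are preserved everywhere — a requirement of the global
subtraction.  With the default 6 residual units the weight-layer count is
1 (multifeature) + 6 x 2 + 1 (reconstruction) = 14.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from ._layers import BatchNorm2d, Conv2d, PReLU

__all__ = ["ModelSpec", "DenoisingNetwork", "tiny_model_spec"]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters.

    ``kernel_plan`` lists (kernel_size, kernel_count) for the parallel
    first-layer convolutions; the counts must sum to ``unit_width``, the
    channel width carried through the residual chain.
    """

    kernel_plan: tuple = ((3, 12), (5, 20), (7, 32))
    n_residual_units: int = 6
    unit_width: int = 64
    in_channels: int = 1
    out_channels: int = 1
    bn_epsilon: float = 1e-5
    bn_momentum: float = 0.9
    prelu_init: float = 0.25
    target: str = "residual"  # "residual" (default) or "clean"

    def __post_init__(self) -> None:
        plan = tuple((int(k), int(c)) for k, c in self.kernel_plan)
        object.__setattr__(self, "kernel_plan", plan)
        if sum(c for _, c in plan) != self.unit_width:
            raise ValueError(
                f"kernel counts {[c for _, c in plan]} must sum to unit_width={self.unit_width}"
            )
        if any(k % 2 == 0 for k, _ in plan):
            raise ValueError("all kernel sizes must be odd")
        if self.n_residual_units < 1:
            raise ValueError("n_residual_units must be >= 1")
        if self.bn_epsilon <= 0:
            raise ValueError("bn_epsilon must be > 0")
        if self.target not in ("residual", "clean"):
            raise ValueError(f"target must be 'residual' or 'clean', got {self.target!r}")

    @property
    def max_kernel_size(self) -> int:
        return max(k for k, _ in self.kernel_plan)

    @property
    def n_weight_layers(self) -> int:
        """Count of layers carrying convolution weights."""
        return 1 + 2 * self.n_residual_units + 1

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        d = json.loads(s)
        d["kernel_plan"] = tuple(tuple(p) for p in d["kernel_plan"])
        return cls(**d)


def tiny_model_spec(n_residual_units: int = 3) -> ModelSpec:
    """A desk-scale spec: same three kernel sizes, 16 channels wide.

    Keeps the multiscale first layer and the residual chain while shrinking
    compute enough for CPU training runs of a few hundred iterations.
    """
    return ModelSpec(
        kernel_plan=((3, 3), (5, 5), (7, 8)),
        n_residual_units=n_residual_units,
        unit_width=16,
    )


class _MultiFeatureLayer:
    """Parallel 3/5/7 convolutions, channel concat, PReLU."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator) -> None:
        self.convs = [
            Conv2d(spec.in_channels, count, ksize, rng=rng)
            for ksize, count in spec.kernel_plan
        ]
        self.act = PReLU(spec.unit_width, init=spec.prelu_init)
        self._splits = np.cumsum([c.out_channels for c in self.convs])[:-1]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        maps = [c.forward(x, train) for c in self.convs]
        return self.act.forward(np.concatenate(maps, axis=1), train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.act.backward(grad)
        parts = np.split(grad, self._splits, axis=1)
        return sum(c.backward(g) for c, g in zip(self.convs, parts))

    def layers(self):
        return [*self.convs, self.act]


class _ResidualUnit:
    """Conv-BN-PReLU-Conv-BN with identity shortcut, then PReLU."""

    def __init__(self, spec: ModelSpec, rng: np.random.Generator) -> None:
        w = spec.unit_width
        self.conv1 = Conv2d(w, w, 3, rng=rng)
        self.bn1 = BatchNorm2d(w, eps=spec.bn_epsilon, momentum=spec.bn_momentum)
        self.act1 = PReLU(w, init=spec.prelu_init)
        self.conv2 = Conv2d(w, w, 3, rng=rng)
        self.bn2 = BatchNorm2d(w, eps=spec.bn_epsilon, momentum=spec.bn_momentum)
        self.act_out = PReLU(w, init=spec.prelu_init)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.conv1.forward(x, train)
        h = self.bn1.forward(h, train)
        h = self.act1.forward(h, train)
        h = self.conv2.forward(h, train)
        h = self.bn2.forward(h, train)
        return self.act_out.forward(h + x, train)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.act_out.backward(grad)
        g = self.bn2.backward(grad)
        g = self.conv2.backward(g)
        g = self.act1.backward(g)
        g = self.bn1.backward(g)
        g = self.conv1.backward(g)
        return g + grad  # shortcut carries the gradient too

    def layers(self):
        return [self.conv1, self.bn1, self.act1, self.conv2, self.bn2, self.act_out]


class DenoisingNetwork:
    """The full residual denoiser.

    Parameters are initialized from a seeded fan-in-scaled Gaussian; the
    reconstruction layer starts at zero so the untrained network is
    exactly the identity map on images (residual == 0, denoised == noisy),
    the natural starting point for residual denoising.
    """

    def __init__(self, spec: ModelSpec | None = None, seed: int = 0) -> None:
        self.spec = spec if spec is not None else ModelSpec()
        rng = np.random.default_rng(seed)
        self.multifeature = _MultiFeatureLayer(self.spec, rng)
        self.units = [_ResidualUnit(self.spec, rng) for _ in range(self.spec.n_residual_units)]
        self.reconstruction = Conv2d(
            self.spec.unit_width, self.spec.out_channels, 3, zero_init=True
        )

    # ----- parameter access -------------------------------------------------

    def layers(self):
        out = self.multifeature.layers()
        for u in self.units:
            out.extend(u.layers())
        out.append(self.reconstruction)
        return out

    def parameters(self) -> list[np.ndarray]:
        return [layer.params[name] for layer in self.layers() for name in sorted(layer.params)]

    def gradients(self) -> list[np.ndarray]:
        return [layer.grads[name] for layer in self.layers() for name in sorted(layer.params)]

    def set_parameters(self, values: list[np.ndarray]) -> None:
        flat = [(layer, name) for layer in self.layers() for name in sorted(layer.params)]
        if len(values) != len(flat):
            raise ValueError("parameter list length mismatch")
        for (layer, name), v in zip(flat, values):
            if layer.params[name].shape != v.shape:
                raise ValueError("parameter shape mismatch")
            layer.params[name] = v.copy()

    def zero_grad(self) -> None:
        for layer in self.layers():
            for name in layer.grads:
                layer.grads[name][...] = 0.0

    # ----- forward / backward -----------------------------------------------

    def _as_batch(self, images: np.ndarray) -> tuple[np.ndarray, bool]:
        x = np.asarray(images, dtype=np.float64)
        single = x.ndim == 2
        if single:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]  # add channel axis
        if x.ndim != 4:
            raise ValueError(f"expected 2-D, 3-D or 4-D input, got shape {images.shape}")
        return x, single

    def forward_features(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.multifeature.forward(x, train)
        for unit in self.units:
            h = unit.forward(h, train)
        return h

    def forward(self, noisy: np.ndarray, train: bool = False) -> tuple[np.ndarray, np.ndarray]:
        """Run the network; return ``(residual, denoised)``.

        Accepts a single 2-D image, a stack ``(n, H, W)``, or a full
        ``(n, c, H, W)`` tensor; output shape mirrors the input.  With the
        default residual target, ``denoised = noisy - residual``; with
        ``target='clean'`` the network output is the clean estimate and the
        residual is derived as ``noisy - output``.
        """
        x, single = self._as_batch(noisy)
        if not np.all(np.isfinite(x)):
            raise ValueError("input contains non-finite values")
        kmax = self.spec.max_kernel_size
        if x.shape[2] < kmax or x.shape[3] < kmax:
            raise ValueError(
                f"input spatial size {x.shape[2]}x{x.shape[3]} is smaller than the "
                f"largest kernel ({kmax}x{kmax})"
            )
        out = self.reconstruction.forward(self.forward_features(x, train), train)
        if self.spec.target == "residual":
            denoised = x - out
        else:
            denoised = out
        # derive the residual from the subtraction so that
        # noisy - denoised == residual holds bit-exactly
        residual = x - denoised
        if single:
            return residual[0, 0], denoised[0, 0]
        if np.asarray(noisy).ndim == 3:
            return residual[:, 0], denoised[:, 0]
        return residual, denoised

    def backward_from_denoised(self, grad_denoised: np.ndarray) -> None:
        """Backpropagate a loss gradient taken w.r.t. the denoised output."""
        g = np.asarray(grad_denoised, dtype=np.float64)
        if g.ndim == 2:
            g = g[None]
        if g.ndim == 3:
            g = g[:, None]
        if self.spec.target == "residual":
            g = -g  # denoised = noisy - residual
        g = self.reconstruction.backward(g)
        for unit in reversed(self.units):
            g = unit.backward(g)
        self.multifeature.backward(g)

    def denoise(self, noisy: np.ndarray) -> np.ndarray:
        """Denoise in evaluation mode; returns only the denoised image(s)."""
        return self.forward(noisy, train=False)[1]
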
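"""Convolution, batch-normalization and PReLU layers with explicit gradients.

Small building blocks for a fully convolutional denoiser, operating on
``(N, C, H, W)`` float64 tensors.  Each layer caches what its backward pass
needs during ``forward`` and accumulates parameter gradients in
``layer.grads`` during ``backward``; ``backward`` returns the gradient with
respect to the layer input.  Convolutions are same-padded (zero padding,
unit stride) so spatial dimensions are preserved end to end — a requirement
of the global residual subtraction.

Convolution is implemented by im2col: sliding windows are flattened so the
convolution (and its weight/input gradients) become dense matrix products.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "BatchNorm2d", "PReLU", "prelu"]


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) of flattened k x k windows."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    # windows[n, c, i, j, :, :] covers xp[n, c, i:i+k, j:j+k]
    win = sliding_window_view(xp, (k, k), axis=(2, 3))
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)


def _col2im(cols: np.ndarray, x_shape: tuple, k: int, pad: int) -> np.ndarray:
    """Scatter-add transpose of :func:`_im2col`."""
    n, c, h, w = x_shape
    cols = cols.reshape(n, h, w, c, k, k)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad))
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + h, j : j + w] += cols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
    if pad == 0:
        return xp
    return xp[:, :, pad:-pad, pad:-pad]


class Conv2d:
    """Same-padded 2-D convolution, unit stride, odd kernel size."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator | None = None,
        zero_init: bool = False,
    ) -> None:
        if kernel_size % 2 == 0:
            raise ValueError(f"kernel size must be odd, got {kernel_size}")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.pad = (kernel_size - 1) // 2
        fan_in = in_channels * kernel_size * kernel_size
        if zero_init:
            w = np.zeros((out_channels, in_channels, kernel_size, kernel_size))
        else:
            if rng is None:
                rng = np.random.default_rng(0)
            # fan-in scaled Gaussian (He-style), suited to rectifier nets
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           size=(out_channels, in_channels, kernel_size, kernel_size))
        self.params = {"weight": w, "bias": np.zeros(out_channels)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        cols = _im2col(x, self.kernel_size, self.pad)
        wmat = self.params["weight"].reshape(self.out_channels, -1)
        out = cols @ wmat.T + self.params["bias"]
        if train:
            self._cache = (cols, x.shape)
        return out.transpose(0, 2, 1).reshape(n, self.out_channels, h, w)

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        cols, x_shape = self._cache
        n, _, h, w = x_shape
        g = grad_out.reshape(n, self.out_channels, h * w).transpose(0, 2, 1)
        gmat = g.reshape(n * h * w, self.out_channels)
        cmat = cols.reshape(n * h * w, -1)
        self.grads["weight"] += (gmat.T @ cmat).reshape(self.params["weight"].shape)
        self.grads["bias"] += gmat.sum(axis=0)
        gcols = g @ self.params["weight"].reshape(self.out_channels, -1)
        return _col2im(gcols, x_shape, self.kernel_size, self.pad)


class BatchNorm2d:
    """Per-channel batch normalization.

    Training mode standardizes each channel with the minibatch mean and
    standard deviation ``sqrt(var + eps)``, then applies the learned
    rescale ``g`` and reshift ``v``, so activations leave the layer with
    per-channel mean v and variance g^2.  Evaluation mode uses running
    statistics accumulated with momentum.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.9) -> None:
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.params = {"g": np.ones(channels), "v": np.zeros(channels)}
        self.grads = {k: np.zeros_like(p) for k, p in self.params.items()}
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        if train:
            if n * h * w < 2:
                raise RuntimeError("batch normalization needs >= 2 samples per channel in train mode")
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu = self.running_mean
            var = self.running_var
        sigma = np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None]) / sigma[:, None, None]
        if train:
            self._cache = (xhat, sigma)
        return self.params["g"][:, None, None] * xhat + self.params["v"][:, None, None]

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        xhat, sigma = self._cache
        n, c, h, w = grad_out.shape
        m = n * h * w
        self.grads["g"] += (grad_out * xhat).sum(axis=(0, 2, 3))
        self.grads["v"] += grad_out.sum(axis=(0, 2, 3))
        dxhat = grad_out * self.params["g"][:, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3))
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3))
        # standard batch-norm input gradient
        dx = (
            dxhat - s1[:, None, None] / m - xhat * s2[:, None, None] / m
        ) / sigma[:, None, None]
        return dx


def prelu(x: np.ndarray | float, k: np.ndarray | float) -> np.ndarray | float:
    """Parametric ReLU: ``x`` where positive, ``k * x`` otherwise.

    ``k = 0`` recovers ReLU; ``k = 1`` is the identity.
    """
    x = np.asarray(x)
    out = np.where(x > 0, x, np.asarray(k) * x)
    return out.item() if out.ndim == 0 else out


class PReLU:
    """Channel-wise PReLU with a learnable negative-branch slope."""

    def __init__(self, channels: int, init: float = 0.25) -> None:
        self.channels = channels
        self.params = {"k": np.full(channels, float(init))}
        self.grads = {"k": np.zeros(channels)}
        self._cache: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        k = self.params["k"][:, None, None]
        out = np.where(x > 0, x, k * x)
        if train:
            self._cache = x
        return out

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        x = self._cache
        k = self.params["k"][:, None, None]
        neg = x <= 0
        self.grads["k"] += (grad_out * x * neg).sum(axis=(0, 2, 3))
        return grad_out * np.where(neg, k, 1.0)
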
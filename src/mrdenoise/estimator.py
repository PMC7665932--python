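"""Scikit-learn-style estimator wrapping the residual denoiser.

``ResidualDenoiser`` is a transformer: ``fit(X, y)`` trains the network on
noisy images ``X`` against clean references ``y``; ``transform(X)``
denoises.  It follows the scikit-learn estimator contract
(``get_params``/``set_params``, fitted attributes with a trailing
underscore, ``clone``-compatible constructor), so it composes with
pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .losses import LossConfig
from .metrics import psnr
from .network import DenoisingNetwork, ModelSpec
from .phantom import ImagePair, NoiseSpec
from .training import TrainConfig, train

__all__ = ["ResidualDenoiser"]


class ResidualDenoiser(TransformerMixin, BaseEstimator):
    """Multifeature-extraction deep residual network MR image denoiser.

    Parameters
    ----------
    kernel_plan : sequence of (kernel_size, count)
        First-layer parallel convolutions; counts must sum to ``unit_width``.
    n_residual_units : int
        Length of the residual-unit chain.
    unit_width : int
        Channel width through the chain.
    optimizer : {"adam", "sgd"}
    learning_rate : float or None
        None resolves to 1e-4 (Adam) or 0.01 (SGD).
    loss : {"mse", "joint"}
        Pixel loss or pixel + ``lam`` x perceptual loss.
    lam : float
        Perceptual-loss weight (joint loss only).
    extractor : str
        Perceptual feature extractor registry name.
    batch_size : int or None
        None resolves to 64 (mse) / 16 (joint).
    epochs, max_iterations : training budget.
    lr_halving_period : float
        Iterations between learning-rate halvings.
    crop_size, crops_per_image : int
        Random training-crop geometry.
    random_state : int
        Seed for weight init, cropping, and shuffling.

    Attributes
    ----------
    network_ : DenoisingNetwork
        The trained network.
    history_ : TrainHistory
        Per-epoch loss (and validation PSNR when a validation set is given).
    n_iter_ : int
        Optimizer steps performed.
    """

    def __init__(
        self,
        kernel_plan=((3, 12), (5, 20), (7, 32)),
        n_residual_units: int = 6,
        unit_width: int = 64,
        bn_epsilon: float = 1e-5,
        prelu_init: float = 0.25,
        optimizer: str = "adam",
        learning_rate: float | None = None,
        loss: str = "mse",
        lam: float = 0.01,
        extractor: str = "fixture",
        batch_size: int | None = None,
        epochs: int = 50,
        max_iterations: int | None = None,
        lr_halving_period: float = 2.0e5,
        crop_size: int = 45,
        crops_per_image: int = 32,
        random_state: int = 0,
    ) -> None:
        self.kernel_plan = kernel_plan
        self.n_residual_units = n_residual_units
        self.unit_width = unit_width
        self.bn_epsilon = bn_epsilon
        self.prelu_init = prelu_init
        self.optimizer = optimizer
        self.learning_rate = learning_rate
        self.loss = loss
        self.lam = lam
        self.extractor = extractor
        self.batch_size = batch_size
        self.epochs = epochs
        self.max_iterations = max_iterations
        self.lr_halving_period = lr_halving_period
        self.crop_size = crop_size
        self.crops_per_image = crops_per_image
        self.random_state = random_state

    # ------------------------------------------------------------------

    def _model_spec(self) -> ModelSpec:
        return ModelSpec(
            kernel_plan=tuple(tuple(p) for p in self.kernel_plan),
            n_residual_units=self.n_residual_units,
            unit_width=self.unit_width,
            bn_epsilon=self.bn_epsilon,
            prelu_init=self.prelu_init,
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            optimizer=self.optimizer,
            initial_lr=self.learning_rate,
            batch_size=self.batch_size,
            epochs=self.epochs,
            max_iterations=self.max_iterations,
            lr_halving_period=self.lr_halving_period,
            loss=self.loss,
            loss_config=LossConfig(lam=self.lam, extractor=self.extractor),
            crop_size=self.crop_size,
            crops_per_image=self.crops_per_image,
            seed=self.random_state,
        )

    @staticmethod
    def _as_image_list(X) -> list[np.ndarray]:
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return [X]
        return [np.asarray(img, dtype=np.float64) for img in X]

    def fit(self, X, y, val_pairs: list[ImagePair] | None = None):
        """Train on noisy images ``X`` with clean references ``y``.

        ``X`` and ``y`` are parallel sequences of 2-D images (or single
        images); shapes must match pairwise.
        """
        noisy = self._as_image_list(X)
        clean = self._as_image_list(y)
        if len(noisy) != len(clean):
            raise ValueError(f"X and y lengths differ: {len(noisy)} vs {len(clean)}")
        pairs = [
            ImagePair(clean=c, noisy=n, noise=NoiseSpec(percent=0.0))
            for n, c in zip(noisy, clean)
        ]
        self.network_ = DenoisingNetwork(self._model_spec(), seed=self.random_state)
        self.history_ = train(self.network_, pairs, self._train_config(), val_pairs=val_pairs)
        self.n_iter_ = self.history_.iterations
        return self

    def transform(self, X):
        """Denoise images; returns a list (or a single 2-D array for 2-D input)."""
        if not hasattr(self, "network_"):
            raise RuntimeError("this ResidualDenoiser instance is not fitted yet")
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return self.network_.denoise(X)
        return [self.network_.denoise(np.asarray(img, dtype=np.float64)) for img in X]

    def predict_residual(self, X):
        """Predicted noise residual(s): ``noisy - denoised``."""
        if not hasattr(self, "network_"):
            raise RuntimeError("this ResidualDenoiser instance is not fitted yet")
        if isinstance(X, np.ndarray) and X.ndim == 2:
            return self.network_.forward(X)[0]
        return [self.network_.forward(np.asarray(img, dtype=np.float64))[0] for img in X]

    def denoise(self, image: np.ndarray) -> np.ndarray:
        """Alias for single-image transform (sweep-evaluation interface)."""
        return self.network_.denoise(image)

    def score(self, X, y) -> float:
        """Mean PSNR (dB) of the denoised images against clean references."""
        denoised = self.transform(X)
        clean = self._as_image_list(y)
        if isinstance(denoised, np.ndarray):
            denoised = [denoised]
        return float(np.mean([psnr(c, d) for c, d in zip(clean, denoised)]))
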
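"""Minibatch training of the residual denoiser.

Training samples random paired crops from the (noisy, clean) image pairs,
shuffles them into minibatches each epoch with a seeded permutation, runs
the network in train mode, and updates the parameters with Adam (default)
or plain SGD under the step-halving learning-rate schedule.  The loss is
either the pixel MSE or the joint pixel+perceptual loss.

Training is a pure function of (initial parameters, dataset, config,
seed): a repeated run reproduces the same history and final parameters on
the same platform.  If the loss goes non-finite, training aborts and the
parameters from the last completed epoch are restored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import metrics as _metrics
from .losses import LossConfig, joint_loss, joint_loss_grad, mse_loss, mse_loss_grad
from .network import DenoisingNetwork
from .optim import AdamState, adam_step, lr_schedule, sgd_step
from .patches import PatchSet, minibatches, random_crops
from .phantom import ImagePair

__all__ = ["TrainConfig", "TrainHistory", "train", "desk_train_config"]

_DEFAULT_LR = {"adam": 1e-4, "sgd": 0.01}
_DEFAULT_BATCH = {"mse": 64, "joint": 16}


@dataclass
class TrainConfig:
    """Optimization settings.

    ``initial_lr`` of None resolves to 1e-4 for Adam and 0.01 for SGD;
    ``batch_size`` of None resolves to 64 for the pixel loss and 16 for
    the joint loss (which is trained with smaller batches).
    ``lr_halving_period`` defaults to the full-scale 2e5 iterations; desk
    runs shrink it together with the iteration budget.
    """

    optimizer: str = "adam"
    initial_lr: float | None = None
    momentum: float = 0.9  # Adam first-moment decay tau1
    tau2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int | None = None
    epochs: int = 50
    max_iterations: int | None = None
    lr_halving_period: float = 2.0e5
    loss: str = "mse"  # "mse" or "joint"
    loss_config: LossConfig = field(default_factory=LossConfig)
    crop_size: int = 45
    crops_per_image: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if self.loss not in ("mse", "joint"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.initial_lr is None:
            self.initial_lr = _DEFAULT_LR[self.optimizer]
        if self.batch_size is None:
            self.batch_size = _DEFAULT_BATCH[self.loss]
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (batch-norm statistics)")
        if self.initial_lr <= 0 or self.lr_halving_period <= 0:
            raise ValueError("rates and periods must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class TrainHistory:
    """Per-epoch training record."""

    epoch_loss: list = field(default_factory=list)
    val_psnr: list = field(default_factory=list)
    iterations: int = 0
    aborted: bool = False


def desk_train_config(**overrides) -> TrainConfig:
    """Desk-scale training defaults for CPU runs of a few hundred steps.

    Uses 32x32 crops, batch 8, Adam at 1e-3 with the halving period scaled
    to 100 iterations — the full-scale schedule (lr 1e-4, halving every
    2e5 steps) compressed proportionally to a 200-step budget.  With 8
    training images the crop pool gives exactly 20 steps per epoch, so 10
    epochs meet the 200-iteration budget.
    """
    cfg = dict(
        optimizer="adam",
        initial_lr=1e-3,
        batch_size=8,
        epochs=10,
        max_iterations=200,
        lr_halving_period=100.0,
        crop_size=32,
        crops_per_image=20,
    )
    cfg.update(overrides)
    return TrainConfig(**cfg)


def _crop_pool(pairs: list[ImagePair], config: TrainConfig, seed: int) -> PatchSet:
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(len(pairs))
    sets = [
        random_crops(
            p,
            crop_size=config.crop_size,
            n=config.crops_per_image,
            seed=int(s.generate_state(1)[0] % (2**31)),
        )
        for p, s in zip(pairs, seeds)
    ]
    return PatchSet.concatenate(sets)


def train(
    network: DenoisingNetwork,
    pairs: list[ImagePair],
    config: TrainConfig | None = None,
    val_pairs: list[ImagePair] | None = None,
) -> TrainHistory:
    """Optimize the network on (noisy, clean) pairs; returns the history.

    The network is updated in place.  ``val_pairs``, if given, are
    denoised after every epoch and the mean PSNR recorded.  With
    ``epochs=0`` or ``max_iterations=0`` the parameters are returned
    unchanged.
    """
    if config is None:
        config = TrainConfig()
    if not pairs:
        raise ValueError("training dataset is empty")
    if config.crop_size > min(min(p.clean.shape) for p in pairs):
        raise ValueError("crop_size exceeds the smallest training image")

    history = TrainHistory()
    if config.epochs == 0 or config.max_iterations == 0:
        return history

    pool = _crop_pool(pairs, config, config.seed)
    adam = AdamState(tau1=config.momentum, tau2=config.tau2, eps=config.adam_eps)

    # optimize the per-pixel-normalized loss: same minimizer as the
    # per-sample sum, but gradient magnitudes are independent of the patch
    # area, so the printed learning rates behave sensibly for SGD
    npix = float(config.crop_size**2)
    if config.loss == "joint":
        loss_fn = lambda d, y: joint_loss(d, y, config.loss_config) / npix
        grad_fn = lambda d, y: joint_loss_grad(d, y, config.loss_config) / npix
    else:
        loss_fn = lambda d, y: mse_loss(d, y) / npix
        grad_fn = lambda d, y: mse_loss_grad(d, y) / npix

    backup = [p.copy() for p in network.parameters()]
    iteration = 0
    for epoch in range(config.epochs):
        losses = []
        for noisy_b, clean_b in minibatches(pool, config.batch_size, seed=config.seed + epoch):
            if config.max_iterations is not None and iteration >= config.max_iterations:
                break
            network.zero_grad()
            _, denoised = network.forward(noisy_b, train=True)
            value = loss_fn(denoised, clean_b)
            if not np.isfinite(value):
                network.set_parameters(backup)
                history.aborted = True
                history.iterations = iteration
                return history
            lr = lr_schedule(iteration, config.initial_lr, config.lr_halving_period)
            try:
                network.backward_from_denoised(grad_fn(denoised, clean_b))
                if config.optimizer == "adam":
                    adam_step(network.parameters(), network.gradients(), adam, lr)
                else:
                    sgd_step(network.parameters(), network.gradients(), lr)
            except FloatingPointError:
                network.set_parameters(backup)
                history.aborted = True
                history.iterations = iteration
                return history
            losses.append(value)
            iteration += 1
        if losses:
            history.epoch_loss.append(float(np.mean(losses)))
            backup = [p.copy() for p in network.parameters()]
        if val_pairs is not None:
            vals = [
                _metrics.psnr(p.clean, network.denoise(p.noisy)) for p in val_pairs
            ]
            history.val_psnr.append(float(np.mean(vals)))
        if config.max_iterations is not None and iteration >= config.max_iterations:
            break
    history.iterations = iteration
    return history
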
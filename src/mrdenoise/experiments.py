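"""Desk-scale reference experiments: training runs and noise-level sweeps.

These runners define the package's standard small-scale study conditions —
8 training phantoms of 64x64, a 16-channel tiny model with 3 residual
units, Adam for 200 iterations — and the noise-level sweep protocol:
following common practice for noise-specific denoisers, one model is
trained per noise intensity and each is evaluated at its own level, which
is what produces the characteristic monotone SSIM-versus-noise table.
A single model trained at one level over-corrects nearly-clean inputs
(it learns the background bias of its training noise), so it is *not*
used across foreign levels in the sweep.

Everything here is a pure function of its seed.
"""

from __future__ import annotations

import numpy as np

from .metrics import MetricsReport, evaluate_sweep, psnr
from .network import DenoisingNetwork, tiny_model_spec
from .phantom import NoiseSpec, make_dataset
from .training import TrainHistory, desk_train_config, train

__all__ = ["run_desk_training", "run_desk_sweep", "NOISE_LEVELS"]

NOISE_LEVELS = (1.0, 4.0, 7.0, 10.0, 13.0)

_N_TRAIN = 8
_N_TEST = 16
_IMG = 64


def run_desk_training(
    percent: float = 7.0,
    seed: int = 1,
    n_residual_units: int = 3,
    optimizer: str = "adam",
    **config_overrides,
) -> tuple[DenoisingNetwork, TrainHistory, dict]:
    """Train the tiny model on 8 synthetic 64x64 phantoms at one noise level.

    Returns ``(network, history, summary)`` where ``summary`` holds the
    held-out noisy-baseline and denoised mean PSNR over 16 fresh phantoms
    corrupted at the same level.
    """
    pairs = make_dataset(_N_TRAIN, _IMG, _IMG, NoiseSpec(percent=percent), seed=seed)
    test = make_dataset(
        _N_TEST, _IMG, _IMG, NoiseSpec(percent=percent), seed=seed + 98
    )
    network = DenoisingNetwork(tiny_model_spec(n_residual_units), seed=seed)
    cfg = desk_train_config(seed=seed, optimizer=optimizer, **config_overrides)
    history = train(network, pairs, cfg)
    summary = {
        "noise_percent": percent,
        "psnr_noisy": float(np.mean([psnr(p.clean, p.noisy) for p in test])),
        "psnr_denoised": float(
            np.mean([psnr(p.clean, network.denoise(p.noisy)) for p in test])
        ),
        "first_epoch_loss": history.epoch_loss[0] if history.epoch_loss else None,
        "last_epoch_loss": history.epoch_loss[-1] if history.epoch_loss else None,
        "iterations": history.iterations,
    }
    return network, history, summary


def run_desk_sweep(
    noise_percents=NOISE_LEVELS, seed: int = 1, models: dict | None = None
) -> tuple[MetricsReport, dict]:
    """Noise-level sweep with level-matched models.

    For each percent, trains (or reuses from ``models``) a tiny model at
    that level and scores it on 16 held-out phantoms corrupted at the same
    level.  Returns the assembled report plus the model dict so callers
    can reuse trained networks.
    """
    if models is None:
        models = {}
    test = make_dataset(_N_TEST, _IMG, _IMG, NoiseSpec(percent=7.0), seed=seed + 98)
    clean = [p.clean for p in test]
    report = MetricsReport(method="level-matched tiny model")
    for percent in sorted(noise_percents):
        if percent not in models:
            models[percent], _, _ = run_desk_training(percent=percent, seed=seed)
        level = evaluate_sweep(
            models[percent], clean, [percent], seed=seed + 4
        )
        report.noise_percents.append(percent)
        report.mean_psnr.append(level.mean_psnr[0])
        report.mean_ssim.append(level.mean_ssim[0])
        report.per_image[percent] = level.per_image[percent]
    return report, models
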
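"""Optimizers (Adam, SGD) and the step-halving learning-rate schedule.

Adam keeps exponential moving averages of the gradient (first moment,
decay ``tau1``) and of the squared gradient (second moment, decay
``tau2``), corrects both for their start-up bias by dividing by
``1 - tau^t``, and steps each parameter by
``-lr * s_hat / (sqrt(v_hat) + eps)``.  SGD is the plain single-rate
update ``theta <- theta - lr * grad``.

The learning-rate schedule halves the initial rate after every
``halving_period`` iterations: ``lr(t) = lr0 * 0.5 ** floor(t / period)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AdamState", "adam_step", "sgd_step", "lr_schedule"]


@dataclass
class AdamState:
    """First/second moment accumulators and step counter for Adam."""

    tau1: float = 0.9
    tau2: float = 0.999
    eps: float = 1e-8
    t: int = 0
    s: list = field(default_factory=list)  # first moments
    v: list = field(default_factory=list)  # second moments

    def __post_init__(self) -> None:
        if not (0 <= self.tau1 < 1 and 0 <= self.tau2 < 1):
            raise ValueError("decay rates must lie in [0, 1)")
        if self.eps <= 0:
            raise ValueError("eps must be > 0")

    def _ensure(self, params: list[np.ndarray]) -> None:
        if not self.s:
            self.s = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]


def _check_finite(grads: list[np.ndarray]) -> None:
    for g in grads:
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(
                "non-finite gradient encountered; training aborted"
            )


def adam_step(
    params: list[np.ndarray],
    grads: list[np.ndarray],
    state: AdamState,
    lr: float,
) -> None:
    """One bias-corrected Adam update, in place.

    ``params`` and ``grads`` are parallel lists of arrays; moments live in
    ``state`` and the step counter is incremented.
    """
    if lr <= 0:
        raise ValueError("learning rate must be > 0")
    _check_finite(grads)
    state._ensure(params)
    state.t += 1
    t = state.t
    c1 = 1.0 - state.tau1**t
    c2 = 1.0 - state.tau2**t
    for p, g, s, v in zip(params, grads, state.s, state.v):
        s *= state.tau1
        s += (1.0 - state.tau1) * g
        v *= state.tau2
        v += (1.0 - state.tau2) * g * g
        p -= lr * (s / c1) / (np.sqrt(v / c2) + state.eps)


def sgd_step(params: list[np.ndarray], grads: list[np.ndarray], lr: float) -> None:
    """Plain gradient-descent update, in place: theta <- theta - lr*grad."""
    if lr < 0:
        raise ValueError("learning rate must be >= 0")
    _check_finite(grads)
    for p, g in zip(params, grads):
        p -= lr * g


def lr_schedule(iteration: int, initial_lr: float = 1e-4, halving_period: float = 2.0e5) -> float:
    """Step-halving schedule: lr0 halved after every ``halving_period`` steps."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    return initial_lr * 0.5 ** int(iteration // halving_period)
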
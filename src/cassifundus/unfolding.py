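"""Deep unfolding: train the fixed-depth ADMM network end to end.

The iterative solver is unrolled to a fixed number of stages (default 4).
Trainable parameters are the per-stage penalties gamma1^i, gamma2^i (kept
positive through a softplus parameterization) and the weights of the
spectral-attention denoiser shared across stages.  Training minimizes the
mean-square error between the unfolded output and the ground-truth cube on
simulated (cube, measurement) pairs, with an Adam optimizer, mini-batch
size 1, and a stepwise learning-rate schedule (constant for the first five
epochs, then decaying by 0.9 every 15 epochs).

The implementation is pure numpy; gradients are obtained by central finite
differences over the (small) parameter vector.  This trades speed for zero
framework dependencies and keeps training fully deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .admm import (
    ADMMState,
    denoise_step,
    guidance_features,
    initialize,
    projection_step,
    update_multipliers,
)
from .denoise import SpectralAttentionDenoiser
from .forward import SensingOperator
from .io import Measurement, SpectralDatacube

__all__ = ["TrainConfig", "UnfoldedADMM", "train_unfolded"]


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _softplus_inv(y: float) -> float:
    return float(np.log(np.expm1(y)))


@dataclass
class TrainConfig:
    """Scaled-down end-to-end training settings."""

    n_stages: int = 4
    epochs: int = 5
    learning_rate: float = 1e-2
    lr_decay: float = 0.9
    lr_decay_every: int = 15
    lr_warm_epochs: int = 5
    fd_step: float = 1e-4
    denoiser_strength: float = 0.1
    seed: int = 0

    def lr_at(self, epoch: int) -> float:
        """Stepwise schedule: constant during warmup, then decay every block."""
        if epoch < self.lr_warm_epochs:
            return self.learning_rate
        blocks = (epoch - self.lr_warm_epochs) // self.lr_decay_every + 1
        return self.learning_rate * self.lr_decay**blocks


class UnfoldedADMM:
    """A fixed-depth unfolded ADMM network with trainable penalties + denoiser."""

    def __init__(
        self,
        op: SensingOperator,
        n_stages: int = 4,
        denoiser_strength: float = 0.1,
        seed: int = 0,
    ):
        self.op = op
        self.n_stages = int(n_stages)
        self.denoiser_strength = float(denoiser_strength)
        self.denoiser = SpectralAttentionDenoiser(
            op.n_bands, n_guidance=op.n_bands + 2, seed=seed
        )
        self._raw_g1 = np.full(self.n_stages, _softplus_inv(1.0))
        self._raw_g2 = np.full(self.n_stages, _softplus_inv(1.0))
        self.loss_history: list[float] = []

    # -- parameters ----------------------------------------------------------
    @property
    def gamma1(self) -> np.ndarray:
        """Per-stage gamma1 (always positive)."""
        return _softplus(self._raw_g1)

    @property
    def gamma2(self) -> np.ndarray:
        """Per-stage gamma2 (always positive)."""
        return _softplus(self._raw_g2)

    def get_params(self) -> np.ndarray:
        return np.concatenate([self._raw_g1, self._raw_g2, self.denoiser.get_params()])

    def set_params(self, params: np.ndarray) -> None:
        n = self.n_stages
        self._raw_g1 = np.asarray(params[:n], dtype=float).copy()
        self._raw_g2 = np.asarray(params[n : 2 * n], dtype=float).copy()
        self.denoiser.set_params(np.asarray(params[2 * n :], dtype=float))

    # -- forward pass --------------------------------------------------------
    def run(self, y: Measurement | np.ndarray) -> np.ndarray:
        """Unfolded reconstruction (raw cube array, not clipped)."""
        y_arr = y.data if isinstance(y, Measurement) else np.asarray(y, dtype=float)
        g1s, g2s = self.gamma1, self.gamma2
        f = initialize(y_arr, self.op, g1s[0], g2s[0])
        lambda1 = np.zeros_like(y_arr)
        lambda2 = np.zeros_like(f)
        for i in range(self.n_stages):
            g1, g2 = g1s[i], g2s[i]
            guide = guidance_features(g2, self.op, y_arr).maps
            v = denoise_step(
                f, lambda2, g2, self.denoiser, self.denoiser_strength, guide
            )
            f = projection_step(v, y_arr, lambda1, lambda2, g1, g2, self.op)
            state = update_multipliers(
                ADMMState(f, v, lambda1, lambda2, g1, g2, i), y_arr, self.op
            )
            lambda1, lambda2 = state.lambda1, state.lambda2
        return f

    def reconstruct(
        self, y: Measurement | np.ndarray, wavelengths: Sequence[float] | None = None
    ) -> SpectralDatacube:
        """Run and wrap as a nonnegative datacube."""
        f = self.run(y)
        if wavelengths is None:
            wavelengths = np.arange(self.op.n_bands, dtype=float)
        return SpectralDatacube(np.clip(f, 0.0, None), np.asarray(wavelengths, float))

    # -- training ------------------------------------------------------------
    def loss(self, pairs: Sequence[tuple[SpectralDatacube, Measurement]]) -> float:
        """Mean MSE over (truth cube, measurement) pairs."""
        total = 0.0
        for cube, y in pairs:
            out = self.run(y)
            total += float(np.mean((out - cube.data) ** 2))
        return total / len(pairs)

    def _sample_grad(
        self, cube: SpectralDatacube, y: Measurement, h: float
    ) -> np.ndarray:
        """Central finite-difference gradient of one sample's MSE."""
        params = self.get_params()
        grad = np.empty_like(params)
        for j in range(params.size):
            for sign, slot in ((+1, 0), (-1, 1)):
                p = params.copy()
                p[j] += sign * h
                self.set_params(p)
                out = self.run(y)
                mse = float(np.mean((out - cube.data) ** 2))
                if slot == 0:
                    plus = mse
                else:
                    minus = mse
            grad[j] = (plus - minus) / (2 * h)
        self.set_params(params)
        return grad

    def train(
        self,
        pairs: Sequence[tuple[SpectralDatacube, Measurement]],
        config: TrainConfig | None = None,
    ) -> list[float]:
        """End-to-end training; returns the per-epoch loss history.

        Mini-batch size 1: one finite-difference gradient and one Adam step
        per training pair per epoch.  Deterministic given the config seed
        (the pair order is shuffled with a seeded generator).
        """
        config = config or TrainConfig()
        rng = np.random.default_rng(config.seed)
        params = self.get_params()
        m = np.zeros_like(params)
        v = np.zeros_like(params)
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        self.loss_history = [self.loss(pairs)]
        for epoch in range(config.epochs):
            lr = config.lr_at(epoch)
            order = rng.permutation(len(pairs))
            for idx in order:
                cube, y = pairs[idx]
                grad = self._sample_grad(cube, y, config.fd_step)
                t += 1
                m = beta1 * m + (1 - beta1) * grad
                v = beta2 * v + (1 - beta2) * grad**2
                m_hat = m / (1 - beta1**t)
                v_hat = v / (1 - beta2**t)
                params = self.get_params() - lr * m_hat / (np.sqrt(v_hat) + eps)
                self.set_params(params)
            self.loss_history.append(self.loss(pairs))
        return self.loss_history


def train_unfolded(
    trainset: Sequence[tuple[SpectralDatacube, Measurement]],
    op: SensingOperator,
    config: TrainConfig | None = None,
) -> UnfoldedADMM:
    """Train a fixed-depth unfolded network on simulated pairs.

    Returns the trained network; its ``denoiser`` and ``gamma1``/``gamma2``
    schedules can be plugged into :class:`~cassifundus.admm.ADMMReconstruction`.
    """
    config = config or TrainConfig()
    net = UnfoldedADMM(
        op,
        n_stages=config.n_stages,
        denoiser_strength=config.denoiser_strength,
        seed=config.seed,
    )
    net.train(trainset, config)
    return net
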
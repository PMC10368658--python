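"""Augmented-Lagrangian / ADMM reconstruction of the spectral datacube.

The snapshot measurement y = Phi f + g is inverted by minimizing
``Psi(f) + (gamma1/2) ||y - Phi f - lambda1/gamma1||^2`` with an auxiliary
split f = v.  Each iteration alternates

1. a denoising subproblem on v (the prior Psi, handled by a pluggable
   denoiser applied to ``f - lambda2/gamma2`` with strength tied to
   1/gamma2),
2. a closed-form quadratic "projection" solve for f — one-shot because
   Phi Phi^T is diagonal (Woodbury identity on the diagonal), and
3. dual (multiplier) updates for lambda1 (data constraint) and lambda2
   (the split).

Penalty parameters gamma1, gamma2 default to 1 for classic priors and may be
given per iteration (e.g. schedules learned by deep unfolding).  Iterates
may go negative; nonnegativity is enforced only on the final output.

Shaped after statsmodels: :class:`ADMMReconstruction` is the model object,
its :meth:`~ADMMReconstruction.fit` returns a :class:`ReconstructionResult`
carrying the cube, the per-iteration data-residual trace, diagnostics and a
``summary()`` table.  The module-level functions expose the individual
algorithm steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.metrics import peak_signal_noise_ratio

from .denoise import Denoiser, IdentityDenoiser, make_denoiser
from .forward import SensingOperator
from .io import Measurement, SpectralDatacube

__all__ = [
    "ADMMState",
    "SolverConfig",
    "GuidanceFeatures",
    "ADMMReconstruction",
    "ReconstructionResult",
    "initialize",
    "projection_step",
    "denoise_step",
    "update_multipliers",
    "guidance_features",
    "reconstruct",
    "psnr",
]


class SolverDivergence(RuntimeError):
    """Raised when the data residual becomes non-finite."""

    def __init__(self, message: str, residuals: list[float]):
        super().__init__(message)
        self.residuals = residuals


@dataclass
class ADMMState:
    """Primal/dual iterates of the solver at iteration ``i``."""

    f: np.ndarray
    v: np.ndarray
    lambda1: np.ndarray
    lambda2: np.ndarray
    gamma1: float
    gamma2: float
    i: int = 0

    def __post_init__(self) -> None:
        if self.gamma1 < 0 or self.gamma2 <= 0:
            raise ValueError("penalties must satisfy gamma1 >= 0, gamma2 > 0")


@dataclass
class SolverConfig:
    """Reconstruction settings.

    ``gamma1``/``gamma2`` may be scalars (constant schedule) or sequences of
    per-iteration values.  ``denoiser_strength`` is the base prior weight;
    the strength passed to the denoiser at iteration i is
    ``denoiser_strength / gamma2_i``.  ``tol`` > 0 adds an early stop on the
    relative change of f (classic-prior mode; unfolding is fixed-depth).
    """

    n_iterations: int = 4
    gamma1: float | Sequence[float] = 1.0
    gamma2: float | Sequence[float] = 1.0
    denoiser: str = "tv"
    denoiser_params: dict = field(default_factory=dict)
    denoiser_strength: float = 0.1
    tol: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be >= 0")

    def gamma_schedule(self) -> tuple[np.ndarray, np.ndarray]:
        def expand(g) -> np.ndarray:
            arr = np.atleast_1d(np.asarray(g, dtype=float))
            if arr.size == 1:
                arr = np.full(self.n_iterations, arr[0])
            if arr.size != self.n_iterations:
                raise ValueError("gamma schedule length must equal n_iterations")
            return arr

        g1, g2 = expand(self.gamma1), expand(self.gamma2)
        if np.any(g1 < 0) or np.any(g2 <= 0):
            raise ValueError("penalties must satisfy gamma1 >= 0, gamma2 > 0")
        return g1, g2


@dataclass
class GuidanceFeatures:
    """Per-pixel feature maps guiding a learned denoiser: (rows, cols, L+2).

    Channel 0 is the constant gamma2 map, channels 1..L are the
    shifted-back mask stack (the transmission pattern each band sees), and
    the last channel is the band-averaged shifted-back diagonal of
    Phi Phi^T.
    """

    maps: np.ndarray

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.maps.shape[:2]


# ---------------------------------------------------------------------------
# algorithm steps (raw-array core)
# ---------------------------------------------------------------------------


def _solve_regularized(
    op: SensingOperator, rhs: np.ndarray, gamma1: float, gamma2: float
) -> np.ndarray:
    """Apply (gamma2 I + gamma1 Phi^T Phi)^{-1} to a cube-shaped rhs.

    Uses the Woodbury identity with the diagonal of Phi Phi^T:
    inverse = (1/gamma2) [I - Phi^T diag(gamma1 / (gamma2 + gamma1 d)) Phi].
    Cost is linear in the number of voxels; no dense matrix is formed.
    """
    if gamma2 <= 0 or gamma1 < 0:
        raise ValueError("penalties must satisfy gamma1 >= 0, gamma2 > 0")
    if gamma1 == 0:
        return rhs / gamma2
    d = op.phi_phit_diag()
    weighted = op.apply(rhs) * (gamma1 / (gamma2 + gamma1 * d))
    return (rhs - op.adjoint_apply(weighted)) / gamma2


def _as_array(y: Measurement | np.ndarray) -> np.ndarray:
    return y.data if isinstance(y, Measurement) else np.asarray(y)


def initialize(
    y: Measurement | np.ndarray,
    op: SensingOperator,
    gamma1: float = 1.0,
    gamma2: float = 1.0,
) -> np.ndarray:
    """Initial estimate f0 = (gamma2 I + gamma1 Phi^T Phi)^{-1} Phi^T y."""
    return _solve_regularized(op, op.adjoint_apply(_as_array(y)), gamma1, gamma2)


def projection_step(
    v: np.ndarray,
    y: Measurement | np.ndarray,
    lambda1: np.ndarray,
    lambda2: np.ndarray,
    gamma1: float,
    gamma2: float,
    op: SensingOperator,
) -> np.ndarray:
    """Closed-form data-fidelity solve for f.

    f = (gamma2 I + gamma1 Phi^T Phi)^{-1}
        [lambda2 + gamma2 v + Phi^T (gamma1 y - lambda1)].
    """
    y_arr = _as_array(y)
    rhs = lambda2 + gamma2 * v + op.adjoint_apply(gamma1 * y_arr - lambda1)
    return _solve_regularized(op, rhs, gamma1, gamma2)


def denoise_step(
    f_prev: np.ndarray,
    lambda2: np.ndarray,
    gamma2: float,
    denoiser: Denoiser,
    strength: float = 0.1,
    guidance: np.ndarray | None = None,
) -> np.ndarray:
    """Prior subproblem: denoise (f - lambda2/gamma2) with weight strength/gamma2."""
    if gamma2 <= 0:
        raise ValueError("gamma2 must be > 0")
    return denoiser.denoise(f_prev - lambda2 / gamma2, strength / gamma2, guidance)


def update_multipliers(
    state: ADMMState, y: Measurement | np.ndarray, op: SensingOperator
) -> ADMMState:
    """Dual ascent on both constraints; increments the iteration index.

    lambda1 <- lambda1 - gamma1 (y - Phi f);  lambda2 <- lambda2 - gamma2 (f - v).
    """
    y_arr = _as_array(y)
    lambda1 = state.lambda1 - state.gamma1 * (y_arr - op.apply(state.f))
    lambda2 = state.lambda2 - state.gamma2 * (state.f - state.v)
    return ADMMState(
        f=state.f,
        v=state.v,
        lambda1=lambda1,
        lambda2=lambda2,
        gamma1=state.gamma1,
        gamma2=state.gamma2,
        i=state.i + 1,
    )


def guidance_features(
    gamma2: float,
    op: SensingOperator,
    y: Measurement | np.ndarray | None = None,
) -> GuidanceFeatures:
    """Raw per-pixel guidance maps: gamma2, mask stack, mean shifted-back diag."""
    rows, cols = op.mask.shape
    L = op.n_bands
    maps = np.empty((rows, cols, L + 2))
    maps[:, :, 0] = gamma2
    d = op.phi_phit_diag()
    trace = np.zeros((rows, cols))
    for k, s in enumerate(op.shifts):
        maps[:, :, 1 + k] = op.mask.pattern
        trace += d[:, s : s + cols]
    maps[:, :, -1] = trace / L
    return GuidanceFeatures(maps)


def psnr(truth: np.ndarray, estimate: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB against the ground-truth range."""
    truth = np.asarray(truth, dtype=np.float64)
    return float(
        peak_signal_noise_ratio(
            truth, np.asarray(estimate, dtype=np.float64), data_range=truth.max()
        )
    )


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class ADMMReconstruction:
    """Reconstruction model: a measurement, its sensing operator, and a prior.

    Parameters
    ----------
    measurement
        The snapshot (``Measurement`` or raw 2-D array) with width
        ``cols + max(shift)``.
    operator
        The :class:`~cassifundus.forward.SensingOperator` used for the
        capture (or its calibration estimate).
    config
        :class:`SolverConfig`; defaults to 4 iterations of the TV prior with
        unit penalties.
    denoiser
        Optional pre-built denoiser instance (overrides ``config.denoiser``),
        e.g. one trained by deep unfolding.
    wavelengths
        Band-center wavelengths for the returned cube; defaults to those
        recorded in the measurement metadata.
    """

    def __init__(
        self,
        measurement: Measurement | np.ndarray,
        operator: SensingOperator,
        config: SolverConfig | None = None,
        denoiser: Denoiser | None = None,
        wavelengths: Sequence[float] | None = None,
    ):
        self.measurement = (
            measurement
            if isinstance(measurement, Measurement)
            else Measurement(np.asarray(measurement))
        )
        if self.measurement.shape != operator.measurement_shape:
            raise ValueError(
                f"measurement shape {self.measurement.shape} does not match "
                f"operator measurement shape {operator.measurement_shape}"
            )
        self.operator = operator
        self.config = config or SolverConfig()
        if denoiser is None:
            denoiser = make_denoiser(
                self.config.denoiser,
                n_bands=operator.n_bands,
                **self.config.denoiser_params,
            )
        self.denoiser = denoiser
        if wavelengths is None:
            wavelengths = self.measurement.meta.get(
                "wavelengths_nm", np.arange(operator.n_bands, dtype=float)
            )
        self.wavelengths = np.asarray(wavelengths, dtype=float)

    def fit(self) -> "ReconstructionResult":
        """Run the solver and return the results object."""
        cfg = self.config
        op = self.operator
        y = self.measurement.data.astype(np.float64)
        g1s, g2s = cfg.gamma_schedule()

        f = initialize(y, op, g1s[0], g2s[0])
        f_init = f.copy()
        lambda1 = np.zeros_like(y)
        lambda2 = np.zeros_like(f)
        v = f.copy()
        use_guidance = hasattr(self.denoiser, "w_gate")
        residuals: list[float] = [float(np.linalg.norm(y - op.apply(f)))]

        for i in range(cfg.n_iterations):
            g1, g2 = g1s[i], g2s[i]
            guide = guidance_features(g2, op, y).maps if use_guidance else None
            v = denoise_step(f, lambda2, g2, self.denoiser, cfg.denoiser_strength, guide)
            f_new = projection_step(v, y, lambda1, lambda2, g1, g2, op)
            state = update_multipliers(
                ADMMState(f_new, v, lambda1, lambda2, g1, g2, i), y, op
            )
            lambda1, lambda2 = state.lambda1, state.lambda2
            res = float(np.linalg.norm(y - op.apply(f_new)))
            residuals.append(res)
            if not np.isfinite(res):
                raise SolverDivergence(
                    f"data residual non-finite at iteration {i + 1}", residuals
                )
            rel_change = np.linalg.norm(f_new - f) / max(np.linalg.norm(f), 1e-30)
            f = f_new
            if cfg.tol > 0 and rel_change < cfg.tol:
                break

        cube = SpectralDatacube(np.clip(f, 0.0, None), self.wavelengths)
        return ReconstructionResult(
            model=self,
            cube=cube,
            initialization=f_init,
            residuals=np.asarray(residuals),
            n_iter=len(residuals) - 1,
        )


@dataclass
class ReconstructionResult:
    """Fitted reconstruction: the cube, residual trace, and diagnostics."""

    model: ADMMReconstruction
    cube: SpectralDatacube
    initialization: np.ndarray
    residuals: np.ndarray
    n_iter: int

    @property
    def data_residual(self) -> float:
        """Final ||y - Phi f||_2."""
        return float(self.residuals[-1])

    def psnr(self, truth: SpectralDatacube | np.ndarray) -> float:
        t = truth.data if isinstance(truth, SpectralDatacube) else np.asarray(truth)
        return psnr(t, self.cube.data)

    def initialization_psnr(self, truth: SpectralDatacube | np.ndarray) -> float:
        t = truth.data if isinstance(truth, SpectralDatacube) else np.asarray(truth)
        return psnr(t, np.clip(self.initialization, 0.0, None))

    def residual_log(self) -> str:
        """Per-iteration residuals as CSV text (iteration 0 = initialization)."""
        lines = ["iteration,data_residual"]
        lines += [f"{i},{r:.10g}" for i, r in enumerate(self.residuals)]
        return "\n".join(lines) + "\n"

    def summary(self) -> str:
        cfg = self.model.config
        rows, cols, L = self.cube.shape
        lines = [
            "ADMM spectral reconstruction",
            "=" * 44,
            f"scene shape           {rows} x {cols} x {L}",
            f"measurement shape     {self.model.measurement.shape[0]} x "
            f"{self.model.measurement.shape[1]}",
            f"denoiser              {type(self.model.denoiser).__name__}",
            f"iterations run        {self.n_iter}",
            f"initial residual      {self.residuals[0]:.6g}",
            f"final data residual   {self.data_residual:.6g}",
            f"residual reduction    {self.residuals[0] / max(self.data_residual, 1e-300):.3g}x",
            f"gamma1 / gamma2       {cfg.gamma1} / {cfg.gamma2}",
        ]
        return "\n".join(lines)

    def plot_residuals(self, ax=None):
        """Semilog plot of the data-residual trace."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(np.arange(len(self.residuals)), self.residuals, marker="o")
        ax.set_xlabel("iteration")
        ax.set_ylabel(r"$\|y - \Phi f\|_2$")
        ax.set_title("ADMM data residual")
        return ax


def reconstruct(
    y: Measurement | np.ndarray,
    op: SensingOperator,
    config: SolverConfig | None = None,
    denoiser: Denoiser | None = None,
    wavelengths: Sequence[float] | None = None,
) -> ReconstructionResult:
    """Functional entry point: build the model and fit it."""
    return ADMMReconstruction(y, op, config, denoiser, wavelengths).fit()
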
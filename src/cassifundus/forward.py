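"""CASSI image formation: mask modulation, spectral shear, sum, and noise.

The snapshot measurement of a spectral datacube f(r, c, k) through a binary
coded aperture T(r, c) and a dispersive prism is

    Y(r, c) = sum_k  f(r, c - s_k, k) * T(r, c - s_k)  +  g(r, c),

where s_k is the integer lateral pixel shift of band k (dispersion along the
column axis, increasing with wavelength) and g is detector noise.  Written on
vectorized arrays this is the linear model y = Phi f + g.  Phi Phi^T is
diagonal, which is what makes the closed-form projection step of the ADMM
solver one-shot; its diagonal is exposed here.

The measurement canvas is extended to ``cols + max(shift)`` columns so the
full dispersed footprint is kept and the adjoint is exact.  Out-of-footprint
pixels are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .dispersion import DispersionModel
from .io import Measurement, SpectralDatacube

__all__ = [
    "CodedMask",
    "NoiseModel",
    "SensingOperator",
    "apply_mask",
    "band_shifts",
    "forward",
    "adjoint",
    "phi_phit_diag",
    "dense_phi",
]


@dataclass
class CodedMask:
    """Binary transmission pattern of the coded aperture.

    ``feature_px`` is the number of sensor pixels spanned by the smallest
    mask feature (2 in the modeled instrument: each chrome feature is
    sampled by about 2 × 2 camera pixels).
    """

    pattern: np.ndarray
    feature_px: int = 2

    def __post_init__(self) -> None:
        self.pattern = np.asarray(self.pattern)
        if self.pattern.ndim != 2:
            raise ValueError("mask pattern must be 2-D")
        if not np.isin(self.pattern, (0, 1)).all():
            raise ValueError("mask pattern values must be in {0, 1}")
        if self.feature_px < 1:
            raise ValueError("feature_px must be >= 1")
        self.pattern = self.pattern.astype(np.float64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pattern.shape

    @property
    def fill_fraction(self) -> float:
        return float(self.pattern.mean())


@dataclass(frozen=True)
class NoiseModel:
    """Detector noise: none, additive Gaussian, or Poisson–Gaussian.

    ``sigma`` is the Gaussian standard deviation in counts; ``gain`` is
    counts per photon for the Poisson branch.  Seeded and reproducible.
    """

    kind: str = "gaussian"
    sigma: float = 0.0
    gain: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "gaussian", "poisson-gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")

    def apply(self, image: np.ndarray) -> np.ndarray:
        if self.kind == "none":
            return image.copy()
        rng = np.random.default_rng(self.seed)
        out = image.astype(np.float64)
        if self.kind == "poisson-gaussian":
            out = rng.poisson(np.clip(out, 0, None) / self.gain) * self.gain
        if self.sigma > 0:
            out = out + rng.normal(0.0, self.sigma, size=out.shape)
        return out


class SensingOperator:
    """The CASSI sensing map Phi: mask, per-band column shift, and sum.

    Parameters
    ----------
    mask
        Binary coded aperture; its pattern shape must equal the scene
        ``(rows, cols)``.
    shifts
        Non-decreasing integer pixel shift per band (length ``n_bands``).
    n_bands
        Number of spectral bands L of the scene the operator acts on.
    """

    def __init__(self, mask: CodedMask, shifts: Sequence[int], n_bands: int | None = None):
        self.mask = mask
        self.shifts = np.asarray(shifts, dtype=int)
        if self.shifts.ndim != 1:
            raise ValueError("shifts must be a 1-D sequence")
        if np.any(np.diff(self.shifts) < 0):
            raise ValueError("shifts must be non-decreasing with band index")
        if np.any(self.shifts < 0):
            raise ValueError("shifts must be nonnegative")
        if n_bands is None:
            n_bands = len(self.shifts)
        if n_bands != len(self.shifts):
            raise ValueError("one shift per band required")
        self.n_bands = int(n_bands)

    @classmethod
    def from_dispersion(
        cls, mask: CodedMask, model: DispersionModel, wavelengths: Iterable[float]
    ) -> "SensingOperator":
        """Build the operator from a prism model and a band grid."""
        return cls(mask, model.band_shifts(wavelengths))

    @classmethod
    def uniform(cls, mask: CodedMask, n_bands: int, step: int = 1) -> "SensingOperator":
        """Uniform shear: band k shifted by ``k * step`` pixels."""
        return cls(mask, step * np.arange(n_bands))

    @property
    def scene_shape(self) -> tuple[int, int, int]:
        r, c = self.mask.shape
        return (r, c, self.n_bands)

    @property
    def measurement_shape(self) -> tuple[int, int]:
        r, c = self.mask.shape
        return (r, c + int(self.shifts.max()))

    def _check_cube(self, data: np.ndarray) -> None:
        if data.shape != self.scene_shape:
            raise ValueError(
                f"cube shape {data.shape} does not match operator scene "
                f"shape {self.scene_shape}"
            )

    def apply(self, cube_data: np.ndarray) -> np.ndarray:
        """Noiseless forward action on raw cube data -> measurement array."""
        self._check_cube(cube_data)
        rows, cols = self.mask.shape
        out = np.zeros(self.measurement_shape, dtype=np.float64)
        masked = cube_data * self.mask.pattern[:, :, None]
        for k, s in enumerate(self.shifts):
            out[:, s : s + cols] += masked[:, :, k]
        return out

    def adjoint_apply(self, meas_data: np.ndarray) -> np.ndarray:
        """Adjoint action Phi^T y -> cube-shaped array."""
        if meas_data.shape != self.measurement_shape:
            raise ValueError(
                f"measurement shape {meas_data.shape} does not match operator "
                f"measurement shape {self.measurement_shape}"
            )
        rows, cols = self.mask.shape
        out = np.empty(self.scene_shape, dtype=np.float64)
        for k, s in enumerate(self.shifts):
            out[:, :, k] = self.mask.pattern * meas_data[:, s : s + cols]
        return out

    def phi_phit_diag(self) -> np.ndarray:
        """diag(Phi Phi^T) as a measurement-shaped array.

        Per measurement pixel this is the sum of squared mask transmissions
        of the contributing bands; for a binary mask, the count of
        transmitting contributing features.
        """
        rows, cols = self.mask.shape
        out = np.zeros(self.measurement_shape, dtype=np.float64)
        sq = self.mask.pattern**2
        for s in self.shifts:
            out[:, s : s + cols] += sq
        return out

    def dense_matrix(self, max_voxels: int = 10_000) -> np.ndarray:
        """Explicit dense Phi (test oracle; refuses large instances).

        Row-major (C-order) vectorization of both cube and measurement:
        ``dense @ cube.ravel() == forward(cube).ravel()``.
        """
        rows, cols, L = self.scene_shape
        if rows * cols * L > max_voxels:
            raise ValueError(
                f"instance with {rows * cols * L} voxels too large for the "
                f"dense oracle (limit {max_voxels})"
            )
        m_rows, m_cols = self.measurement_shape
        dense = np.zeros((m_rows * m_cols, rows * cols * L))
        r, c, k = np.meshgrid(
            np.arange(rows), np.arange(cols), np.arange(L), indexing="ij"
        )
        col_idx = (r * cols + c) * L + k  # voxel index, C order
        row_idx = r * m_cols + (c + self.shifts[k])
        dense[row_idx.ravel(), col_idx.ravel()] = np.repeat(
            self.mask.pattern[:, :, None], L, axis=2
        ).ravel()
        return dense


def apply_mask(cube: SpectralDatacube, mask: CodedMask) -> SpectralDatacube:
    """Modulate every band of the cube elementwise by the coded aperture."""
    if mask.shape != cube.data.shape[:2]:
        raise ValueError(
            f"mask shape {mask.shape} does not match cube spatial shape "
            f"{cube.data.shape[:2]}"
        )
    return SpectralDatacube(cube.data * mask.pattern[:, :, None], cube.wavelengths)


def band_shifts(model: DispersionModel, wavelengths: Iterable[float]) -> np.ndarray:
    """Integer pixel shift of each band center relative to the reference."""
    return model.band_shifts(wavelengths)


def forward(
    cube: SpectralDatacube,
    op: SensingOperator,
    noise: NoiseModel | None = None,
) -> Measurement:
    """Simulate the snapshot measurement y = Phi f + g."""
    clean = op.apply(cube.data)
    meta = {
        "shifts": op.shifts.tolist(),
        "scene_shape": list(op.scene_shape),
        "wavelengths_nm": cube.wavelengths.tolist(),
    }
    if noise is not None and noise.kind != "none":
        meta["noise"] = {
            "kind": noise.kind,
            "sigma": noise.sigma,
            "gain": noise.gain,
            "seed": noise.seed,
        }
        clean = noise.apply(clean)
    return Measurement(clean, meta)


def adjoint(measurement: Measurement, op: SensingOperator) -> SpectralDatacube:
    """Apply Phi^T to a measurement, returning a cube-shaped result.

    The result may contain zeros where the mask blocks; wavelengths are not
    tracked by the operator, so the measurement's recorded band grid is used
    when available and a unit grid otherwise.
    """
    data = op.adjoint_apply(measurement.data)
    wavelengths = measurement.meta.get(
        "wavelengths_nm", np.arange(op.n_bands, dtype=float)
    )
    # adjoint output can be negative for noisy y; wrap without cube validation
    return SpectralDatacube._unvalidated(data, np.asarray(wavelengths, dtype=float))


def phi_phit_diag(op: SensingOperator) -> np.ndarray:
    """Diagonal of Phi Phi^T (measurement-shaped)."""
    return op.phi_phit_diag()


def dense_phi(op: SensingOperator, max_voxels: int = 10_000) -> np.ndarray:
    """Dense matrix form of Phi for small instances (test oracle)."""
    return op.dense_matrix(max_voxels=max_voxels)
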
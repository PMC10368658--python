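"""Pluggable denoising priors for the ADMM denoising subproblem.

The prior half of each ADMM iteration is a proximal/denoising problem: given
a noisy cube estimate, return a cleaner one.  Any object with a
``denoise(data, strength, guidance=None)`` method works; ``strength`` is the
regularization weight (the solver ties it to ``1/gamma2``), and as
``strength -> 0`` every denoiser must approach the identity.

Implementations:

* :class:`TVDenoiser` — isotropic spatial total variation, band by band,
  via Chambolle's dual algorithm (scikit-image), 20 inner iterations by
  default.
* :class:`WaveletDenoiser` — per-band wavelet soft-thresholding.
* :class:`IdentityDenoiser` — no prior (data-fidelity-only unfolding).
* :class:`SpectralAttentionDenoiser` — a small trainable stand-in for a
  spectral-transformer denoiser: channel-wise self-attention over bands from
  per-band summary descriptors, a shared 3 × 3 convolutional spatial-mixing
  kernel, and an optional guidance gate.  Pure numpy; its parameters are
  trained end-to-end by the unfolding trainer.
"""

from __future__ import annotations

from typing import Protocol

import numpy as np
import pywt
from scipy import ndimage
from skimage.restoration import denoise_tv_chambolle

__all__ = [
    "Denoiser",
    "TVDenoiser",
    "WaveletDenoiser",
    "IdentityDenoiser",
    "SpectralAttentionDenoiser",
    "make_denoiser",
    "tv_objective",
]


class Denoiser(Protocol):
    def denoise(
        self, data: np.ndarray, strength: float, guidance: np.ndarray | None = None
    ) -> np.ndarray: ...


def tv_objective(data: np.ndarray) -> float:
    """Isotropic spatial TV functional, summed over bands (diagnostic)."""
    dx = np.diff(data, axis=1, prepend=data[:, :1])
    dy = np.diff(data, axis=0, prepend=data[:1])
    return float(np.sqrt(dx**2 + dy**2).sum())


class TVDenoiser:
    """Band-wise isotropic spatial TV prior (Chambolle dual algorithm)."""

    def __init__(self, inner_iterations: int = 20):
        self.inner_iterations = int(inner_iterations)

    def denoise(
        self, data: np.ndarray, strength: float, guidance: np.ndarray | None = None
    ) -> np.ndarray:
        if strength <= 0:
            return data.copy()
        out = np.empty_like(data, dtype=np.float64)
        for k in range(data.shape[2]):
            out[:, :, k] = denoise_tv_chambolle(
                data[:, :, k].astype(np.float64),
                weight=strength,
                max_num_iter=self.inner_iterations,
            )
        return out


class WaveletDenoiser:
    """Per-band soft-thresholding of wavelet detail coefficients."""

    def __init__(self, wavelet: str = "db4", level: int | None = None):
        self.wavelet = wavelet
        self.level = level

    def denoise(
        self, data: np.ndarray, strength: float, guidance: np.ndarray | None = None
    ) -> np.ndarray:
        if strength <= 0:
            return data.copy()
        out = np.empty_like(data, dtype=np.float64)
        for k in range(data.shape[2]):
            band = data[:, :, k].astype(np.float64)
            coeffs = pywt.wavedec2(band, self.wavelet, level=self.level)
            thresholded = [coeffs[0]] + [
                tuple(pywt.threshold(c, strength, mode="soft") for c in detail)
                for detail in coeffs[1:]
            ]
            rec = pywt.waverec2(thresholded, self.wavelet)
            out[:, :, k] = rec[: band.shape[0], : band.shape[1]]
        return out


class IdentityDenoiser:
    """The trivial prior: returns its input."""

    def denoise(
        self, data: np.ndarray, strength: float, guidance: np.ndarray | None = None
    ) -> np.ndarray:
        return data.copy()


def _softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class SpectralAttentionDenoiser:
    """Trainable spectral-attention denoiser (numpy, residual form).

    Bands are treated as tokens.  Each band k yields a 2-vector descriptor
    (spatial mean, spatial std); learned query/key projections of the
    descriptors give an L x L band-attention matrix; attended bands are
    spatially mixed by a shared 3 x 3 kernel.  The residual is optionally
    gated per pixel by a linear map of the guidance features and scaled by
    ``strength``, so strength -> 0 recovers the identity.

    Parameters are exposed as a flat vector (:meth:`get_params` /
    :meth:`set_params`) for the finite-difference unfolding trainer.
    """

    attn_dim = 4

    def __init__(self, n_bands: int, n_guidance: int | None = None, seed: int = 0):
        self.n_bands = int(n_bands)
        self.n_guidance = int(n_guidance) if n_guidance is not None else n_bands + 2
        rng = np.random.default_rng(seed)
        d = self.attn_dim
        self.w_query = 0.1 * rng.standard_normal((2, d))
        self.w_key = 0.1 * rng.standard_normal((2, d))
        kernel = 0.01 * rng.standard_normal((3, 3))
        kernel[1, 1] += 1.0  # near-delta init: starts close to identity mixing
        self.kernel = kernel
        self.w_gate = np.zeros(self.n_guidance)
        self.log_scale = np.log(0.5)

    # -- flat parameter vector ------------------------------------------------
    def get_params(self) -> np.ndarray:
        return np.concatenate(
            [
                self.w_query.ravel(),
                self.w_key.ravel(),
                self.kernel.ravel(),
                self.w_gate,
                [self.log_scale],
            ]
        )

    def set_params(self, params: np.ndarray) -> None:
        d = self.attn_dim
        sizes = [2 * d, 2 * d, 9, self.n_guidance, 1]
        if params.size != sum(sizes):
            raise ValueError(f"expected {sum(sizes)} parameters, got {params.size}")
        chunks = np.split(np.asarray(params, dtype=float), np.cumsum(sizes)[:-1])
        self.w_query = chunks[0].reshape(2, d)
        self.w_key = chunks[1].reshape(2, d)
        self.kernel = chunks[2].reshape(3, 3)
        self.w_gate = chunks[3]
        self.log_scale = float(chunks[4][0])

    @property
    def n_params(self) -> int:
        return 4 * self.attn_dim + 9 + self.n_guidance + 1

    # -- forward --------------------------------------------------------------
    def denoise(
        self, data: np.ndarray, strength: float, guidance: np.ndarray | None = None
    ) -> np.ndarray:
        if strength <= 0:
            return data.copy()
        x = data.astype(np.float64)
        desc = np.stack([x.mean(axis=(0, 1)), x.std(axis=(0, 1))], axis=1)  # (L, 2)
        q = desc @ self.w_query
        k = desc @ self.w_key
        attn = _softmax(q @ k.T / np.sqrt(self.attn_dim), axis=1)  # (L, L)
        attended = np.einsum("rck,lk->rcl", x, attn)
        mixed = ndimage.convolve(attended, self.kernel[:, :, None], mode="nearest")
        residual = mixed - x
        if guidance is not None:
            gate = 1.0 / (1.0 + np.exp(-(guidance @ self.w_gate)))
            residual = residual * gate[:, :, None]
        return x + strength * np.exp(self.log_scale) * residual


def make_denoiser(name: str, n_bands: int | None = None, **params) -> Denoiser:
    """Factory used by the solver config: tv | wavelet | identity | spectral-attention."""
    name = name.lower().replace("_", "-")
    if name in ("tv", "total-variation"):
        return TVDenoiser(**params)
    if name == "wavelet":
        return WaveletDenoiser(**params)
    if name in ("identity", "none"):
        return IdentityDenoiser()
    if name in ("spectral-attention", "learned"):
        if n_bands is None:
            raise ValueError("spectral-attention denoiser needs n_bands")
        return SpectralAttentionDenoiser(n_bands, **params)
    raise ValueError(f"unknown denoiser {name!r}")
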
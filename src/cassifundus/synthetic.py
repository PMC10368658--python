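"""Synthetic masks and test scenes with known ground truth.

Everything the imaging chain needs is generated here, seeded and
deterministic: random binary coded masks on a feature grid, a rainbow
scene (spatially varying narrowband illumination, emulating a linear
variable filter), three-bar resolution-chart scenes, a flat field, and an
eye phantom — a smooth fundus-like background crossed by a branching
vessel raster whose absorber has the oxyhemoglobin double peak at 540 and
575 nm.

Default band grid: 445–600 nm in 32 bands (5-nm spacing), the visible
range and channel count regime of the modeled instrument at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_dilation, gaussian_filter
from skimage.draw import disk

from .forward import CodedMask
from .io import SpectralDatacube
from .spectra import RegionOfInterest, Spectrum

__all__ = [
    "SceneSpec",
    "random_binary_mask",
    "rainbow_scene",
    "bar_target_scene",
    "eye_phantom_scene",
    "flat_scene",
    "oxyhemoglobin_like_absorption",
]

#: Default two-Gaussian absorber: (center_nm, sigma_nm, amplitude) per lobe.
#: Centers are the oxyhemoglobin absorption peaks; widths are chosen so the
#: summed absorber still attains its discrete maxima exactly at 540 and
#: 575 nm on a 5-nm band grid despite lobe overlap.
OXY_LOBES: tuple[tuple[float, float, float], ...] = (
    (540.0, 12.0, 0.6),
    (575.0, 10.0, 0.5),
)


@dataclass
class SceneSpec:
    """Scene geometry and band grid shared by all generators."""

    rows: int = 64
    cols: int = 64
    bands: int = 32
    lambda_min: float = 445.0
    lambda_max: float = 600.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bands < 1:
            raise ValueError("need at least one band")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("scene must have positive spatial size")
        if self.lambda_max <= self.lambda_min and self.bands > 1:
            raise ValueError("wavelength range must be increasing")

    @property
    def wavelengths(self) -> np.ndarray:
        if self.bands == 1:
            return np.array([self.lambda_min])
        return np.linspace(self.lambda_min, self.lambda_max, self.bands)


def random_binary_mask(
    rows: int,
    cols: int,
    fill_fraction: float = 0.5,
    feature_px: int = 2,
    seed: int = 0,
) -> CodedMask:
    """I.i.d. Bernoulli pattern on the feature grid, upsampled to pixels."""
    if not (0 < fill_fraction < 1):
        raise ValueError("fill_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    gr = -(-rows // feature_px)  # ceil division
    gc = -(-cols // feature_px)
    grid = (rng.random((gr, gc)) < fill_fraction).astype(np.uint8)
    pattern = np.kron(grid, np.ones((feature_px, feature_px), dtype=np.uint8))
    return CodedMask(pattern[:rows, :cols], feature_px=feature_px)


def rainbow_scene(spec: SceneSpec, bandwidth_nm: float = 10.0) -> SpectralDatacube:
    """Glyph silhouettes under a laterally sweeping narrowband illumination.

    Each column is lit by a Gaussian spectral band whose center sweeps
    linearly from ``lambda_min`` (left edge) to ``lambda_max`` (right
    edge) — the action of a linear variable filter.  ``bandwidth_nm`` is
    the Gaussian FWHM (the emulated filter passes 7–20 nm).
    """
    wl = spec.wavelengths
    centers = np.linspace(spec.lambda_min, spec.lambda_max, spec.cols)
    sigma = max(bandwidth_nm, 1e-6) / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    weights = np.exp(-((wl[None, :] - centers[:, None]) ** 2) / (2 * sigma**2))
    silhouette = _glyph_silhouette(spec.rows, spec.cols)
    data = silhouette[:, :, None] * weights[None, :, :]
    peak = data.max()
    if peak > 0:
        data = data / peak
    return SpectralDatacube(data, wl)


def _glyph_silhouette(rows: int, cols: int) -> np.ndarray:
    """A few simple shapes spread along the columns (letter-object stand-in)."""
    img = np.zeros((rows, cols))
    r0 = rows // 2
    radius = max(2, rows // 8)
    for frac in (0.2, 0.5, 0.8):
        rr, cc = disk((r0, int(frac * (cols - 1))), radius, shape=img.shape)
        img[rr, cc] = 1.0
    # a horizontal bar linking the glyphs
    img[r0 - max(1, rows // 32) : r0 + max(1, rows // 32), cols // 10 : -cols // 10] = 1.0
    return img


def bar_target_scene(
    spec: SceneSpec,
    groups_lpmm: Sequence[float],
    pixel_pitch_um: float,
) -> SpectralDatacube:
    """Three-bar chart patterns at the given spatial frequencies.

    Each group renders three dark-bright bar pairs horizontally and,
    transposed, vertically; the scene is spectrally flat.  The bar period
    in pixels is ``1000 / (lp/mm) / pixel_pitch_um`` and must be at least 2.
    """
    if pixel_pitch_um <= 0:
        raise ValueError("pixel pitch must be positive")
    img = np.zeros((spec.rows, spec.cols))
    row = 1
    for f in groups_lpmm:
        period_px = 1000.0 / f / pixel_pitch_um
        if period_px < 2:
            raise ValueError(
                f"{f} lp/mm gives a period of {period_px:.2f} px — unrepresentable"
            )
        half = max(1, int(round(period_px / 2)))
        block = _three_bars(half)
        h, w = block.shape
        if row + h > spec.rows or 1 + w + 1 + h > spec.cols:
            raise ValueError("bar groups do not fit in the scene")
        img[row : row + h, 1 : 1 + w] = block  # horizontal bars
        img[row : row + w, 1 + w + 1 : 1 + w + 1 + h] = block.T  # vertical bars
        row += max(h, w) + 2
    data = np.repeat(img[:, :, None], spec.bands, axis=2)
    return SpectralDatacube(data, spec.wavelengths)


def _three_bars(half_period: int) -> np.ndarray:
    """Three bright bars of width ``half_period`` separated by equal gaps."""
    length = 5 * half_period  # bar height (standard 5:1 aspect)
    width = 5 * half_period  # 3 bars + 2 gaps
    block = np.zeros((width, length))
    for b in range(3):
        block[2 * b * half_period : (2 * b + 1) * half_period, :] = 1.0
    return block


def flat_scene(spec: SceneSpec, level: float = 1.0) -> SpectralDatacube:
    """Spatially and spectrally uniform scene (white-target stand-in)."""
    if level < 0:
        raise ValueError("level must be nonnegative")
    return SpectralDatacube(
        np.full((spec.rows, spec.cols, spec.bands), float(level)), spec.wavelengths
    )


def oxyhemoglobin_like_absorption(
    wavelengths: np.ndarray,
    lobes: Sequence[tuple[float, float, float]] = OXY_LOBES,
    extinction_csv: str | Path | None = None,
) -> np.ndarray:
    """Absorber A(lambda) in [0, 1): two Gaussians at the oxyhemoglobin peaks.

    A user-supplied ``extinction_csv`` (columns ``wavelength_nm,extinction``)
    replaces the Gaussian model; it is interpolated onto the band grid and
    max-normalized to the summed Gaussian amplitude.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if extinction_csv is not None:
        ext = Spectrum.from_csv(extinction_csv)
        interp = np.interp(wl, ext.wavelengths, ext.values)
        peak = interp.max()
        amp = max(a for _, _, a in lobes)
        return interp / peak * amp if peak > 0 else interp
    out = np.zeros_like(wl)
    for center, sigma, amplitude in lobes:
        out += amplitude * np.exp(-((wl - center) ** 2) / (2 * sigma**2))
    return out


def _vessel_map(rows: int, cols: int, rng: np.random.Generator) -> np.ndarray:
    """Seeded branching random-walk raster, dilated to vessel thickness.

    Main vessels enter from the border and meander with small angular
    jitter, occasionally branching.  New vessels are launched until the
    dilated raster covers at least ~2.5% of the frame (walks that exit
    early otherwise leave too sparse a pattern), targeting the 2–10%
    vessel-pixel fraction of a fundus field of view.
    """
    canvas = np.zeros((rows, cols), dtype=bool)
    cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    target = 0.025 * rows * cols

    def launch() -> tuple[float, float, float, int]:
        side = int(rng.integers(4))
        if side == 0:
            return 0.0, float(rng.uniform(0, cols)), float(rng.uniform(0.3, 2.8)), int(0.7 * max(rows, cols))
        if side == 1:
            return float(rows - 1), float(rng.uniform(0, cols)), float(rng.uniform(-2.8, -0.3)), int(0.7 * max(rows, cols))
        if side == 2:
            return float(rng.uniform(0, rows)), 0.0, float(rng.uniform(-1.2, 1.2)), int(0.7 * max(rows, cols))
        return float(rng.uniform(0, rows)), float(cols - 1), float(np.pi + rng.uniform(-1.2, 1.2)), int(0.7 * max(rows, cols))

    stack: list[tuple[float, float, float, int]] = [launch(), launch()]
    launches = 2
    while stack:
        r, c, ang, steps = stack.pop()
        for _ in range(steps):
            r += float(np.sin(ang))
            c += float(np.cos(ang))
            if not (0 <= r < rows and 0 <= c < cols):
                break
            canvas[int(r), int(c)] = True
            ang += float(rng.normal(0.0, 0.18))
            if rng.random() < 0.01 and len(stack) < 6:
                stack.append(
                    (r, c, ang + float(rng.choice([-1, 1])) * float(rng.uniform(0.5, 1.0)), steps // 2)
                )
        # dilation roughly triples coverage; keep launching until dense enough
        if not stack and 3 * canvas.sum() < target and launches < 12:
            stack.append(launch())
            launches += 1
    return binary_dilation(canvas, structure=cross)


def eye_phantom_scene(
    spec: SceneSpec,
    lobes: Sequence[tuple[float, float, float]] = OXY_LOBES,
    extinction_csv: str | Path | None = None,
) -> tuple[SpectralDatacube, RegionOfInterest, Spectrum]:
    """Fundus-like phantom: smooth background with absorbing vessels.

    The cube is ``background(r, c) * (1 - A(lambda) * vessel(r, c))`` with a
    spectrally flat, spatially smooth background reflectance and the
    oxyhemoglobin-like absorber A.  Returns the cube, the vessel pixel mask
    as a region of interest, and the true mean vessel reflectance spectrum
    for recovery checks.
    """
    rng = np.random.default_rng(spec.seed)
    background = gaussian_filter(rng.random((spec.rows, spec.cols)), sigma=8.0)
    lo, hi = background.min(), background.max()
    background = 0.6 + 0.4 * (background - lo) / max(hi - lo, 1e-12)
    vessels = _vessel_map(spec.rows, spec.cols, rng)
    if not vessels.any():  # pathological seed: force a minimal vessel
        vessels[spec.rows // 2, :] = True
    absorber = oxyhemoglobin_like_absorption(
        spec.wavelengths, lobes=lobes, extinction_csv=extinction_csv
    )
    data = background[:, :, None] * (
        1.0 - absorber[None, None, :] * vessels[:, :, None].astype(float)
    )
    cube = SpectralDatacube(np.clip(data, 0.0, None), spec.wavelengths)
    roi = RegionOfInterest(vessels)
    truth = Spectrum(spec.wavelengths.copy(), cube.data[vessels].mean(axis=0))
    return cube, roi, truth
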
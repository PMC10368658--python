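"""Spectral/spatial resolution calibration and mask extraction.

Spectral resolution: the smallest coded-mask feature spans ``feature_px``
camera pixels (2 in the modeled instrument), so the resolution of a band is
the local prism dispersion (nm/pixel) times ``feature_px`` — the spectral
span that moves a mask image by one feature.  The system-level figure is the
range-width-weighted mean over the dispersion segments.

Spatial resolution: three-bar resolution-chart groups are scored by the
Michelson contrast (I_max - I_min)/(I_max + I_min) of a line profile across
the bars; the finest group with contrast above a threshold (default 0.4) is
the resolvable limit, and its line-pair period in µm is 1000/(lp/mm).

Mask calibration: a capture of the coded aperture under uniform
monochromatic illumination is binarized with Otsu's global threshold.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from .dispersion import DispersionModel
from .forward import CodedMask
from .io import Measurement

__all__ = [
    "LineProfile",
    "ResolutionReport",
    "spectral_resolution",
    "average_spectral_resolution",
    "lpmm_to_micron",
    "contrast",
    "resolvable_limit",
    "mask_from_monochromatic",
]


def _round_half_up(x: float, decimals: int = 1) -> float:
    scale = 10**decimals
    return math.floor(x * scale + 0.5) / scale


@dataclass
class LineProfile:
    """Intensity profile across a bar group (positions in pixels)."""

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.size < 3:
            raise ValueError("line profile needs at least 3 samples")
        if self.positions.size != self.intensities.size:
            raise ValueError("positions and intensities must have equal length")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")


@dataclass
class ResolutionReport:
    """Calibration summary, serializable to JSON."""

    band_resolutions_nm: dict[str, float]
    average_resolution_nm: int
    average_resolution_nm_exact: float
    spatial_horizontal_um: float | None = None
    spatial_vertical_um: float | None = None
    contrasts: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "band_resolutions_nm": self.band_resolutions_nm,
                "average_resolution_nm": self.average_resolution_nm,
                "average_resolution_nm_exact": self.average_resolution_nm_exact,
                "spatial_horizontal_um": self.spatial_horizontal_um,
                "spatial_vertical_um": self.spatial_vertical_um,
                "contrasts": self.contrasts,
            },
            indent=2,
        )


def spectral_resolution(nm_per_pixel: float, feature_px: int = 2) -> float:
    """Band spectral resolution in nm, rounded half-up to one decimal."""
    if nm_per_pixel <= 0 or feature_px <= 0:
        raise ValueError("nm_per_pixel and feature_px must be positive")
    return _round_half_up(nm_per_pixel * feature_px, 1)


def average_spectral_resolution(
    model: DispersionModel, feature_px: int = 2
) -> tuple[int, float]:
    """Range-width-weighted mean resolution over the dispersion segments.

    Returns ``(rounded_nm, exact_nm)``; the headline figure is the nearest
    integer nm.
    """
    if feature_px <= 0:
        raise ValueError("feature_px must be positive")
    widths = np.array([hi - lo for lo, hi, _ in model.segments])
    if widths.sum() <= 0:
        raise ValueError("empty wavelength range")
    res = np.array([d * feature_px for _, _, d in model.segments])
    exact = float((widths * res).sum() / widths.sum())
    return int(_round_half_up(exact, 0)), exact


def lpmm_to_micron(frequency_lpmm: float) -> float:
    """Line-pair period in µm for a spatial frequency in lp/mm (one decimal)."""
    if frequency_lpmm <= 0:
        raise ValueError("frequency must be positive")
    return _round_half_up(1000.0 / frequency_lpmm, 1)


def contrast(profile: LineProfile) -> float:
    """Michelson contrast (I_max - I_min)/(I_max + I_min) of a profile."""
    i_max = float(profile.intensities.max())
    i_min = float(profile.intensities.min())
    if i_max <= 0:
        raise ValueError("contrast undefined for an all-zero profile")
    return (i_max - i_min) / (i_max + i_min)


def resolvable_limit(
    group_contrasts: dict[float, float], threshold: float = 0.4
) -> float | None:
    """Highest spatial frequency whose contrast meets the threshold.

    Returns ``None`` when no group is resolved.
    """
    if not group_contrasts:
        raise ValueError("no bar groups supplied")
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    passing = [f for f, c in group_contrasts.items() if c >= threshold]
    return max(passing) if passing else None


def mask_from_monochromatic(
    image: Measurement | np.ndarray, feature_px: int = 2
) -> CodedMask:
    """Recover the coded mask from a monochromatic flat-field capture.

    Binarizes with Otsu's global threshold.  The transmitting fraction is a
    sanity flag: a random binary mask is nominally near 50% open, so a
    fraction outside [0.4, 0.6] (e.g. an inverted-contrast capture of an
    unbalanced mask) emits a warning.
    """
    data = image.data if isinstance(image, Measurement) else np.asarray(image)
    if data.max() == data.min():
        raise ValueError("cannot threshold a uniform calibration image")
    t = threshold_otsu(data.astype(np.float64))
    pattern = (data > t).astype(np.uint8)
    fill = float(pattern.mean())
    if not (0.4 <= fill <= 0.6):
        warnings.warn(
            f"transmitting fraction {fill:.3f} far from the nominal 0.5 — "
            "check illumination uniformity and contrast polarity",
            UserWarning,
            stacklevel=2,
        )
    return CodedMask(pattern, feature_px=feature_px)
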
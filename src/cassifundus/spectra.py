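"""Reflectance / illumination / absorption spectra and peak analysis.

The tissue absorption spectrum is the normalized-difference of the lamp
illumination spectrum S_i and a region-averaged reflectance spectrum S_r:

    S_a = S_i / max(S_i) - S_r / max(S_r).

Where reflectance dips (e.g. hemoglobin absorption in a retinal vessel),
S_a peaks; oxygenated hemoglobin shows its characteristic double peak near
540 and 575 nm.  Peak analysis applies a light 3-point moving average and
ranks local maxima by prominence.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import find_peaks

from .io import SpectralDatacube

__all__ = [
    "Spectrum",
    "RegionOfInterest",
    "field_average_spectrum",
    "absorption_spectrum",
    "find_absorption_peaks",
]


@dataclass
class Spectrum:
    """Intensity versus wavelength (relative units)."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape or self.wavelengths.ndim != 1:
            raise ValueError("wavelengths and values must be equal-length 1-D arrays")
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return self.wavelengths.size

    def to_csv(self, path: str | Path | None = None) -> str:
        """Serialize as ``wavelength_nm,value`` CSV; optionally write to path."""
        buf = _io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(["wavelength_nm", "value"])
        for w, v in zip(self.wavelengths, self.values):
            writer.writerow([w, v])
        text = buf.getvalue()
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_csv(cls, path: str | Path) -> "Spectrum":
        with Path(path).open() as fh:
            rows = list(csv.DictReader(fh))
        return cls(
            np.array([float(r["wavelength_nm"]) for r in rows]),
            np.array([float(r["value"]) for r in rows]),
        )


@dataclass
class RegionOfInterest:
    """Boolean pixel mask over (rows, cols); at least one pixel selected."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValueError("ROI selects no pixels")

    @classmethod
    def circle(
        cls, rows: int, cols: int, center: tuple[float, float], radius: float
    ) -> "RegionOfInterest":
        r, c = np.ogrid[:rows, :cols]
        return cls((r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius**2)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def field_average_spectrum(
    cube: SpectralDatacube, roi: RegionOfInterest | None = None
) -> Spectrum:
    """Per-band mean over the ROI (full frame when ROI is omitted)."""
    if roi is None:
        values = cube.data.mean(axis=(0, 1))
    else:
        if roi.mask.shape != cube.data.shape[:2]:
            raise ValueError(
                f"ROI shape {roi.mask.shape} does not match cube spatial shape "
                f"{cube.data.shape[:2]}"
            )
        values = cube.data[roi.mask].mean(axis=0)
    return Spectrum(cube.wavelengths.copy(), values)


def absorption_spectrum(s_r: Spectrum, s_i: Spectrum) -> Spectrum:
    """Normalized-difference absorption: S_i/max(S_i) - S_r/max(S_r)."""
    if len(s_r) != len(s_i) or not np.allclose(s_r.wavelengths, s_i.wavelengths):
        raise ValueError("reflectance and illumination wavelength grids differ")
    max_i, max_r = s_i.values.max(), s_r.values.max()
    if max_i <= 0 or max_r <= 0:
        raise ValueError("spectra must have a positive maximum to normalize")
    return Spectrum(s_r.wavelengths.copy(), s_i.values / max_i - s_r.values / max_r)


def find_absorption_peaks(
    s_a: Spectrum, window_nm: float = 10.0, with_prominence: bool = False
) -> list[float] | list[tuple[float, float]]:
    """Local maxima of a (lightly smoothed) absorption spectrum.

    A 3-point moving average suppresses single-sample jitter; peaks closer
    than ``window_nm`` are merged (the more prominent one wins).  Returns
    band-center wavelengths sorted by descending prominence (optionally
    ``(wavelength_nm, prominence)`` pairs); a monotone spectrum yields an
    empty list.
    """
    if len(s_a) < 5:
        raise ValueError("need at least 5 samples for peak analysis")
    smoothed = np.convolve(s_a.values, np.ones(3) / 3, mode="same")
    # edge samples average only two points; restore proper means
    smoothed[0] = s_a.values[:2].mean()
    smoothed[-1] = s_a.values[-2:].mean()
    step = float(np.median(np.diff(s_a.wavelengths)))
    distance = max(1, int(round(window_nm / step)))
    idx, props = find_peaks(smoothed, distance=distance, prominence=0.0)
    order = np.argsort(props["prominences"])[::-1]
    if with_prominence:
        return [
            (float(s_a.wavelengths[idx[j]]), float(props["prominences"][j]))
            for j in order
        ]
    return [float(s_a.wavelengths[idx[j]]) for j in order]
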
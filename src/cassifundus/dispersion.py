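"""Prism dispersion model: wavelength-dependent lateral pixel shift.

A wedge prism disperses the coded image along the column axis; because the
dispersion is nonlinear in wavelength, the model is piecewise: a list of
contiguous wavelength intervals each with a constant local dispersion in
nm per sensor pixel.  The pixel shift of a band is the integral of
``1 / (nm per pixel)`` from a reference wavelength (zero-shift anchor, by
convention the short end of the range) up to the band center, rounded to the
nearest integer pixel.

The packaged default table covers 445–602 nm in four segments (1.67, 2.00,
2.50, 3.33 nm/pixel), the measured dispersion of a 10° wedge prism at the
camera plane of the instrument this package models.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "DispersionModel",
    "load_dispersion_csv",
    "save_dispersion_csv",
    "default_prism",
]


@dataclass(frozen=True)
class DispersionModel:
    """Piecewise-constant prism dispersion (nm per pixel) over wavelength.

    Parameters
    ----------
    segments
        Sequence of ``(lambda_lo_nm, lambda_hi_nm, nm_per_pixel)`` triples;
        intervals must be contiguous and dispersion strictly positive.
    reference_wavelength
        Wavelength (nm) at which the lateral shift is defined to be zero.
        Defaults to the low end of the covered range.
    """

    segments: tuple[tuple[float, float, float], ...]
    reference_wavelength: float | None = None

    def __post_init__(self) -> None:
        segs = tuple(
            (float(lo), float(hi), float(d)) for lo, hi, d in self.segments
        )
        if not segs:
            raise ValueError("dispersion model needs at least one segment")
        for lo, hi, d in segs:
            if hi <= lo:
                raise ValueError(f"empty segment [{lo}, {hi}]")
            if d <= 0:
                raise ValueError("dispersion must be positive")
        for (_, hi, _), (lo2, _, _) in zip(segs, segs[1:]):
            if abs(hi - lo2) > 1e-9:
                raise ValueError("segments must be contiguous")
        object.__setattr__(self, "segments", segs)
        ref = self.reference_wavelength
        if ref is None:
            ref = segs[0][0]
        ref = float(ref)
        if not (segs[0][0] <= ref <= segs[-1][1]):
            raise ValueError("reference wavelength outside covered range")
        object.__setattr__(self, "reference_wavelength", ref)

    @property
    def lambda_min(self) -> float:
        return self.segments[0][0]

    @property
    def lambda_max(self) -> float:
        return self.segments[-1][1]

    def nm_per_pixel(self, wavelength: float) -> float:
        """Local dispersion at ``wavelength`` (nm/pixel)."""
        self._check_range(wavelength)
        for lo, hi, d in self.segments:
            if lo <= wavelength <= hi:
                return d
        raise AssertionError("unreachable")

    def pixel_shift(self, wavelength: float) -> float:
        """Signed continuous shift in pixels relative to the reference.

        Integrates ``dλ / (nm per pixel)`` from the reference wavelength.
        """
        self._check_range(wavelength)
        ref = self.reference_wavelength
        lo_w, hi_w = min(ref, wavelength), max(ref, wavelength)
        shift = 0.0
        for lo, hi, d in self.segments:
            overlap = min(hi, hi_w) - max(lo, lo_w)
            if overlap > 0:
                shift += overlap / d
        return shift if wavelength >= ref else -shift

    def band_shifts(self, wavelengths: Iterable[float]) -> np.ndarray:
        """Integer pixel shift per band; non-decreasing with wavelength."""
        shifts = np.array(
            [int(round(self.pixel_shift(w))) for w in wavelengths], dtype=int
        )
        if np.any(np.diff(shifts) < 0):
            raise ValueError("band shifts must be non-decreasing in wavelength")
        return shifts

    def _check_range(self, wavelength: float) -> None:
        if not (self.lambda_min <= wavelength <= self.lambda_max):
            raise ValueError(
                f"wavelength {wavelength} nm outside modeled range "
                f"[{self.lambda_min}, {self.lambda_max}] nm"
            )


def load_dispersion_csv(path: str | Path) -> DispersionModel:
    """Load a dispersion table CSV (lambda_lo_nm, lambda_hi_nm, nm_per_pixel)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dispersion table not found: {path}")
    with path.open() as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        raise ValueError(f"empty dispersion table: {path}")
    segments = tuple(
        (float(r["lambda_lo_nm"]), float(r["lambda_hi_nm"]), float(r["nm_per_pixel"]))
        for r in rows
    )
    return DispersionModel(segments)


def save_dispersion_csv(model: DispersionModel, path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["lambda_lo_nm", "lambda_hi_nm", "nm_per_pixel"])
        for lo, hi, d in model.segments:
            writer.writerow([lo, hi, d])


def default_prism() -> DispersionModel:
    """The packaged 445–602 nm wedge-prism dispersion table."""
    ref = resources.files("cassifundus").joinpath("data/prism_dispersion.csv")
    with resources.as_file(ref) as path:
        return load_dispersion_csv(path)
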
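"""Spectral datacube, measurement, and mask serialization.

Cubes are stored as multi-page grayscale TIFF (one page per band, pages in
ascending wavelength order) with a JSON sidecar ``<file>.json`` holding the
wavelength axis; the sidecar is authoritative.  Measurements are single-page
TIFF (uint16 for integer data, float32 otherwise) with an optional provenance
sidecar.  Masks are 8-bit PNG (0/255).

Axis convention: arrays are indexed ``(row, col, band)``, 0-based.  The
column axis is the dispersion axis.  Radiometry is relative throughout —
no absolute calibration is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "SpectralDatacube",
    "Measurement",
    "SensorGeometry",
    "save_cube",
    "load_cube",
    "save_measurement",
    "load_measurement",
    "save_mask_image",
    "load_mask_image",
]


def _sidecar_path(path: Path) -> Path:
    return Path(str(path) + ".json")


@dataclass
class SpectralDatacube:
    """A 3-D spectral datacube ``(rows, cols, bands)`` with a wavelength axis.

    Parameters
    ----------
    data
        Nonnegative, finite array of shape ``(rows, cols, bands)`` in
        arbitrary radiometric units.
    wavelengths
        Strictly increasing band-center wavelengths in nm, one per band.
    """

    data: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"cube data must be 3-D, got shape {self.data.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.data.shape[2]:
            raise ValueError(
                f"wavelength count {self.wavelengths.size} does not match "
                f"band count {self.data.shape[2]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube data contains non-finite values")
        if np.any(self.data < 0):
            raise ValueError("cube data contains negative values")
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @classmethod
    def _unvalidated(cls, data: np.ndarray, wavelengths: np.ndarray) -> "SpectralDatacube":
        """Wrap intermediate (possibly negative) solver arrays without checks."""
        obj = cls.__new__(cls)
        obj.data = np.asarray(data)
        obj.wavelengths = np.asarray(wavelengths, dtype=float)
        return obj

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    def band(self, k: int) -> np.ndarray:
        return self.data[:, :, k]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectralDatacube):
            return NotImplemented
        return np.array_equal(self.data, other.data) and np.array_equal(
            self.wavelengths, other.wavelengths
        )


@dataclass
class Measurement:
    """A 2-D snapshot detector image in counts, plus provenance metadata.

    The measurement canvas is wider than the scene: ``cols + max(shift)``
    columns hold the full dispersed footprint.
    """

    data: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"measurement must be 2-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("measurement contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class SensorGeometry:
    """Detector geometry: pixel pitch in µm and pixel counts."""

    pixel_pitch_um: float
    rows: int
    cols: int

    def __post_init__(self) -> None:
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel pitch must be positive")
        if self.rows < 1 or self.cols < 1:
            raise ValueError("sensor must have at least one pixel per axis")


def save_cube(cube: SpectralDatacube, path: str | Path) -> None:
    """Write a cube as multi-page TIFF plus a JSON wavelength sidecar.

    Integer cubes round-trip bit-exactly; floating cubes are stored as
    float32 (relative round-trip error ≤ 1e-6).
    """
    path = Path(path)
    data = cube.data
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    pages = np.moveaxis(data, 2, 0)  # (bands, rows, cols)
    # explicit photometric: 3-page stacks must not be guessed as RGB
    tifffile.imwrite(path, pages, photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps({"wavelengths_nm": list(map(float, cube.wavelengths))})
    )


def load_cube(path: str | Path) -> SpectralDatacube:
    """Read a cube written by :func:`save_cube`.

    Raises ``FileNotFoundError`` with a "wavelengths unavailable" message
    when the sidecar is missing, and a validation error when page count and
    wavelength count disagree.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"wavelengths unavailable: missing sidecar {sidecar}"
        )
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    wavelengths = json.loads(sidecar.read_text())["wavelengths_nm"]
    if len(wavelengths) != pages.shape[0]:
        raise ValueError(
            f"sidecar lists {len(wavelengths)} wavelengths but file has "
            f"{pages.shape[0]} pages"
        )
    return SpectralDatacube(np.moveaxis(pages, 0, 2), np.asarray(wavelengths))


def save_measurement(m: Measurement, path: str | Path) -> None:
    """Write a measurement as single-page TIFF with a provenance sidecar."""
    path = Path(path)
    data = m.data
    if np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    tifffile.imwrite(path, data)
    _sidecar_path(path).write_text(json.dumps({"meta": _jsonable(m.meta)}))


def load_measurement(path: str | Path) -> Measurement:
    """Read a measurement; the sidecar is optional (meta defaults to {})."""
    path = Path(path)
    data = tifffile.imread(path)
    meta: dict[str, Any] = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text()).get("meta", {})
    return Measurement(np.asarray(data), meta)


def save_mask_image(pattern: np.ndarray, path: str | Path) -> None:
    """Write a binary mask pattern as an 8-bit PNG (0/255)."""
    pattern = np.asarray(pattern)
    if not np.isin(pattern, (0, 1)).all():
        raise ValueError("mask pattern must be binary {0,1}")
    iio.imwrite(Path(path), (pattern.astype(np.uint8) * 255))


def load_mask_image(path: str | Path) -> np.ndarray:
    """Read a mask PNG/TIFF and binarize at half the maximum level."""
    img = np.asarray(iio.imread(Path(path)))
    if img.ndim == 3:  # collapse RGB(A)
        img = img[..., 0]
    if img.max() == img.min():
        raise ValueError("degenerate mask image: uniform values")
    return (img > (int(img.max()) + int(img.min())) / 2).astype(np.uint8)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
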
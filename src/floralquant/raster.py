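"""Raster containers, image I/O, radiometric correction and color conversion.

Field images enter the pipeline as 3-band 8-bit rasters (RGB from consumer
cameras, or NIR/G/B and R/G/NIR from band-modified cameras).  A small
diffuse-reflectance panel of known nominal reflectance photographed in the
scene anchors radiometric correction: each band is multiplied by the gain
that maps the panel's observed mean to its nominal reflectance, removing
between-image illumination differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from skimage import color as _skcolor

log = logging.getLogger(__name__)

RAW_8BIT = "raw_8bit"
REFLECTANCE = "reflectance"

#: pixel values slightly above 1 can occur after correction when a scene
#: region outshines the panel; they are clipped here and flagged, not dropped
REFLECTANCE_CEILING = 1.5

VALID_BANDS = ("R", "G", "B", "NIR")


class RasterFormatError(ValueError):
    """Raised for undecodable files, wrong channel counts or bad band labels."""


class DegeneratePanelError(ValueError):
    """Raised when a panel region has zero mean in some band."""


@dataclass
class PanelSpec:
    """Axis-aligned reference-panel rectangle with nominal reflectance.

    ``row_start/row_stop/col_start/col_stop`` follow half-open numpy slice
    convention.  ``reflectance`` is either a scalar applied to every band or
    one value per band, all in (0, 1].
    """

    row_start: int
    row_stop: int
    col_start: int
    col_stop: int
    reflectance: float | Sequence[float] = 0.99

    def __post_init__(self) -> None:
        if self.row_stop <= self.row_start or self.col_stop <= self.col_start:
            raise ValueError("panel region is empty")
        refl = np.atleast_1d(np.asarray(self.reflectance, dtype=float))
        if refl.size not in (1, 3) or np.any(refl <= 0) or np.any(refl > 1):
            raise ValueError("panel reflectance must be in (0, 1], scalar or per-band")

    def per_band(self) -> np.ndarray:
        refl = np.atleast_1d(np.asarray(self.reflectance, dtype=float))
        return np.repeat(refl, 3) if refl.size == 1 else refl

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_start, self.row_stop), slice(self.col_start, self.col_stop)


@dataclass
class RasterImage:
    """3-band pixel raster with band labels, value scale and optional GSD.

    ``scale`` is ``raw_8bit`` (values in [0, 255]) or ``reflectance``
    (values in [0, 1.5], small >1 overshoot from correction tolerated).
    ``gsd_mm`` is the ground sample distance, millimetres per pixel.
    """

    pixels: np.ndarray
    bands: tuple[str, ...] = ("R", "G", "B")
    scale: str = RAW_8BIT
    gsd_mm: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise RasterFormatError(
                f"expected an H x W x 3 raster, got shape {self.pixels.shape}"
            )
        self.bands = tuple(self.bands)
        if len(self.bands) != 3 or any(b not in VALID_BANDS for b in self.bands):
            raise RasterFormatError(f"bands must be 3 labels from {VALID_BANDS}")
        if not np.all(np.isfinite(self.pixels)):
            raise RasterFormatError("pixel values must be finite")
        if self.scale == RAW_8BIT:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise RasterFormatError("raw_8bit values must lie in [0, 255]")
        elif self.scale == REFLECTANCE:
            if self.pixels.min() < 0 or self.pixels.max() > REFLECTANCE_CEILING:
                raise RasterFormatError(
                    f"reflectance values must lie in [0, {REFLECTANCE_CEILING}]"
                )
        else:
            raise RasterFormatError(f"unknown scale {self.scale!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def band(self, name: str) -> np.ndarray:
        try:
            return self.pixels[:, :, self.bands.index(name)]
        except ValueError:
            raise KeyError(f"band {name!r} not in {self.bands}") from None


def load_image(path: str | Path, bands: Sequence[str] = ("R", "G", "B")) -> RasterImage:
    """Decode a 3-channel PNG/TIFF/JPEG into a raw_8bit :class:`RasterImage`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # undecodable payload
        raise RasterFormatError(f"cannot decode {path}: {exc}") from exc
    if arr.ndim == 3 and arr.shape[2] == 4:  # tolerate opaque alpha
        if np.all(arr[:, :, 3] == arr[:, :, 3].flat[0]):
            arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise RasterFormatError(
            f"{path} has shape {arr.shape}; a 3-channel image is required"
        )
    return RasterImage(arr.astype(float), bands=tuple(bands), scale=RAW_8BIT)


def save_image(img: RasterImage, path: str | Path) -> None:
    """Write an 8-bit 3-channel PNG/TIFF; reflectance images are scaled by 255."""
    px = img.pixels
    if img.scale == REFLECTANCE:
        px = np.clip(px, 0.0, 1.0) * 255.0
    iio.imwrite(Path(path), np.round(px).astype(np.uint8))


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask as a single-band 8-bit PNG (0/255)."""
    iio.imwrite(Path(path), (np.asarray(mask, bool).astype(np.uint8) * 255))


def save_overlay(img: RasterImage, mask: np.ndarray, path: str | Path) -> None:
    """Write the image with mask pixels painted white (quality-inspection view)."""
    px = img.pixels.copy()
    top = 1.0 if img.scale == REFLECTANCE else 255.0
    px[np.asarray(mask, bool)] = top
    save_image(replace(img, pixels=px), path)


def radiometric_correct(img: RasterImage, panel: PanelSpec) -> RasterImage:
    """Scale each band so the reference panel maps to its nominal reflectance.

    The per-band gain is ``nominal_reflectance / mean(panel pixels)``.  Output
    is on the reflectance scale; values above 1 (scene brighter than panel)
    are tolerated up to 1.5, clipped, and logged.
    """
    if img.scale != RAW_8BIT:
        raise ValueError("radiometric correction expects a raw_8bit image")
    rs, cs = panel.slices()
    h, w = img.shape
    if panel.row_stop > h or panel.col_stop > w:
        raise ValueError("panel region exceeds image bounds")
    panel_mean = img.pixels[rs, cs].reshape(-1, 3).mean(axis=0)
    if np.any(panel_mean == 0):
        raise DegeneratePanelError(f"panel mean is zero in some band: {panel_mean}")
    gain = panel.per_band() / panel_mean
    out = img.pixels * gain
    n_over = int(np.count_nonzero(out > 1.0))
    if n_over:
        log.warning("radiometric correction: %d pixels exceed reflectance 1.0", n_over)
    out = np.clip(out, 0.0, REFLECTANCE_CEILING)
    return RasterImage(out, bands=img.bands, scale=REFLECTANCE, gsd_mm=img.gsd_mm)


def rescale_to_unit(img: RasterImage) -> RasterImage:
    """Min-max rescale the whole raster (globally, not per band) onto [0, 1].

    A constant image maps to all zeros.
    """
    lo, hi = img.pixels.min(), img.pixels.max()
    px = np.zeros_like(img.pixels) if hi == lo else (img.pixels - lo) / (hi - lo)
    return RasterImage(px, bands=img.bands, scale=REFLECTANCE, gsd_mm=img.gsd_mm)


def rgb_to_lab(img: RasterImage) -> np.ndarray:
    """Convert an R,G,B raster to CIE L*a*b* (sRGB companding, D65 white).

    Returns an H x W x 3 float array with L* in [0, 100] and signed a*, b*.
    Rasters containing a NIR band are rejected: the conversion is defined
    only for true color.
    """
    if tuple(img.bands) != ("R", "G", "B"):
        raise RasterFormatError(
            f"CIE L*a*b* conversion requires R,G,B bands, got {img.bands}"
        )
    rgb = img.pixels / 255.0 if img.scale == RAW_8BIT else np.clip(img.pixels, 0.0, 1.0)
    return _skcolor.rgb2lab(rgb)
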
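"""Calibrated grayscale image container and file I/O.

A :class:`GrayImage` couples a 2-D intensity raster with the physical pixel
size (µm per pixel edge). The calibration travels with the image through the
whole preprocessing chain because the downstream particle-size filter is
specified in µm² and is meaningless without it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import InputError, ParameterError

logger = logging.getLogger(__name__)

__all__ = ["GrayImage", "read_image", "write_image"]


@dataclass
class GrayImage:
    """2-D non-negative intensity raster with µm-per-pixel calibration.

    Parameters
    ----------
    pixels
        2-D array of intensities; any integer or floating dtype is accepted
        and converted to float64 for internal arithmetic.
    pixel_size_um
        Physical edge length of one pixel in µm. Must be positive; there is
        deliberately no default because the 10 µm² object-size cutoff depends
        on it.
    """

    pixels: np.ndarray
    pixel_size_um: float = field()

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise InputError(f"expected a non-empty 2-D raster, got shape {arr.shape}")
        arr = arr.astype(np.float64, copy=False)
        if not np.all(np.isfinite(arr)):
            raise InputError("image contains non-finite intensities")
        if arr.min() < 0:
            raise InputError("image contains negative intensities")
        if not (np.isfinite(self.pixel_size_um) and self.pixel_size_um > 0):
            raise ParameterError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        self.pixels = arr
        self.pixel_size_um = float(self.pixel_size_um)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def pixel_area_um2(self) -> float:
        """Area of one pixel in µm²."""
        return self.pixel_size_um**2

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        """Return a new image with the same calibration and new pixel data."""
        return GrayImage(pixels=pixels, pixel_size_um=self.pixel_size_um)


def _collapse_channels(arr: np.ndarray, path: Path) -> np.ndarray:
    """Reduce a multi-channel raster to its first channel, with a warning."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3:
        # channel axis is whichever axis is small (RGB(A) or C-first stacks)
        if arr.shape[-1] <= 4:
            logger.warning("%s has %d channels; using the first", path, arr.shape[-1])
            return arr[..., 0]
        if arr.shape[0] <= 4:
            logger.warning("%s has %d channels; using the first", path, arr.shape[0])
            return arr[0]
    raise InputError(f"{path}: unsupported image shape {arr.shape}")


def read_image(path: str | Path, pixel_size_um: float) -> GrayImage:
    """Read a single-channel TIFF or PNG micrograph.

    Multi-channel files are reduced to their first channel with a logged
    warning. The caller supplies the µm/px calibration; it is not read from
    file metadata.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = _collapse_channels(np.asarray(arr), path)
    return GrayImage(pixels=arr, pixel_size_um=pixel_size_um)


def write_image(path: str | Path, img: GrayImage, dtype: str = "float32") -> None:
    """Write an image as TIFF (float32 by default, or uint16 with clipping)."""
    path = Path(path)
    if dtype == "uint16":
        data = np.clip(np.rint(img.pixels), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    elif dtype == "float32":
        data = img.pixels.astype(np.float32)
    else:
        raise ParameterError(f"unsupported export dtype: {dtype}")
    tifffile.imwrite(path, data)
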
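"""Mean-method auto-thresholding and size-filtered particle analysis.

A preprocessed image is binarized at its arithmetic-mean intensity (bright
neurites on dark background), connected components are labeled, and objects
below the 10 µm² size cutoff are discarded. Per-image summary statistics
(object count, mean object size, total neurite-covered area) feed the
fragmentation and integrity metrics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure

from .errors import InputError, ParameterError
from .image import GrayImage

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryMask",
    "ObjectTable",
    "ImageStats",
    "threshold_mean",
    "label_objects",
    "filter_min_size",
    "image_stats",
]

OBJECT_COLUMNS = ["label", "area_px", "area_um2", "centroid_row", "centroid_col"]


@dataclass
class BinaryMask:
    """Boolean foreground raster with inherited µm/px calibration."""

    pixels: np.ndarray
    pixel_size_um: float
    threshold: float | None = None  # intensity used to produce the mask, if any

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2 or arr.size == 0:
            raise InputError(f"expected a non-empty 2-D mask, got shape {arr.shape}")
        self.pixels = arr.astype(bool, copy=False)
        if not (np.isfinite(self.pixel_size_um) and self.pixel_size_um > 0):
            raise ParameterError(f"pixel_size_um must be positive, got {self.pixel_size_um}")


@dataclass
class ObjectTable:
    """Per-connected-component records of one image.

    ``table`` has one row per object with columns ``label``, ``area_px``,
    ``area_um2`` (= area_px · pixel_size_um²) and the intensity-unweighted
    centroid in (row, col) pixel coordinates.
    """

    table: pd.DataFrame
    pixel_size_um: float

    def __post_init__(self) -> None:
        missing = [c for c in OBJECT_COLUMNS if c not in self.table.columns]
        if missing:
            raise InputError(f"ObjectTable missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.table)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, columns=OBJECT_COLUMNS)


@dataclass(frozen=True)
class ImageStats:
    """Image-level particle summary.

    ``mean_size_um2`` is NaN when the image has no objects; the missing value
    propagates into the integrity statistic rather than being zero-filled.
    """

    count: int
    mean_size_um2: float
    total_area_um2: float

    @property
    def has_objects(self) -> bool:
        return self.count > 0


def threshold_mean(img: GrayImage) -> BinaryMask:
    """Binarize at the arithmetic-mean intensity of the whole image.

    Foreground is the strictly-greater-than-mean side, i.e. the bright
    structures (calcein / RFP labeled neurites on a dark background). A
    constant image yields an empty foreground, which is legal and logged.
    """
    t = float(img.pixels.mean())
    fg = img.pixels > t
    if not fg.any():
        logger.warning("mean threshold %.4g produced an empty foreground", t)
    return BinaryMask(pixels=fg, pixel_size_um=img.pixel_size_um, threshold=t)


def label_objects(mask: BinaryMask, connectivity: int = 8) -> ObjectTable:
    """Connected-component particle extraction.

    ``connectivity`` is 8 (default; diagonal neighbors connect, the
    particle-analysis convention) or 4. Labels are contiguous from 1.
    """
    if connectivity not in (4, 8):
        raise ParameterError(f"connectivity must be 4 or 8, got {connectivity}")
    skimage_conn = 1 if connectivity == 4 else 2
    labels = measure.label(mask.pixels, connectivity=skimage_conn)
    props = measure.regionprops(labels)
    px_area = mask.pixel_size_um**2
    rows = [
        {
            "label": p.label,
            "area_px": int(p.area),
            "area_um2": float(p.area) * px_area,
            "centroid_row": float(p.centroid[0]),
            "centroid_col": float(p.centroid[1]),
        }
        for p in props
    ]
    table = pd.DataFrame(rows, columns=OBJECT_COLUMNS)
    return ObjectTable(table=table, pixel_size_um=mask.pixel_size_um)


def filter_min_size(objects: ObjectTable, min_area_um2: float = 10.0) -> ObjectTable:
    """Drop objects smaller than ``min_area_um2`` (inclusive cutoff: area ≥
    min is kept, the "size = min–Infinity" convention). Labels and row order
    are preserved — no relabeling."""
    if not (np.isfinite(min_area_um2) and min_area_um2 > 0):
        raise ParameterError(f"min_area_um2 must be positive, got {min_area_um2}")
    kept = objects.table[objects.table["area_um2"] >= min_area_um2].reset_index(drop=True)
    return ObjectTable(table=kept, pixel_size_um=objects.pixel_size_um)


def image_stats(objects: ObjectTable) -> ImageStats:
    """Count, mean object size (µm²) and total object area (µm²) of one image.

    The total area is the "neurite-covered area" used for well QC; the mean
    size is NaN (missing) for object-free images.
    """
    n = len(objects.table)
    total = float(objects.table["area_um2"].sum()) if n else 0.0
    mean = total / n if n else math.nan
    return ImageStats(count=n, mean_size_um2=mean, total_area_um2=total)
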
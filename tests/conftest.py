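"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the code paths they check: morphology by
explicit per-pixel window scans, connected components by breadth-first flood
fill, convolution by direct kernel sums.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np
import pytest

from axoquant import (
    COMPACT_BACKGROUND_RADIUS_PX,
    FieldParams,
    GrayImage,
    ImageStats,
    PreprocessParams,
    compact_field_params,
    filter_min_size,
    image_stats,
    label_objects,
    preprocess,
    threshold_mean,
)

PIXEL_SIZE_UM = 0.5  # calibration used throughout the test suite


# ----------------------------------------------------------------------------
# brute-force oracles


def ball_offsets(radius: float) -> list[tuple[int, int, float]]:
    """(dy, dx, height) triples of the discrete ball structuring element."""
    r_int = math.ceil(radius)
    out = []
    for dy in range(-r_int, r_int + 1):
        for dx in range(-r_int, r_int + 1):
            d2 = dy * dy + dx * dx
            if d2 <= radius * radius:
                out.append((dy, dx, math.sqrt(radius * radius - d2)))
    return out


def brute_ball_opening(pixels: np.ndarray, radius: float) -> np.ndarray:
    """Grayscale opening with a ball element, edge-replicated borders,
    computed by explicit window scans (erosion then dilation)."""
    offsets = ball_offsets(radius)
    r_int = math.ceil(radius)
    h, w = pixels.shape
    padded = np.pad(pixels, r_int, mode="edge")
    eroded = np.empty_like(pixels, dtype=float)
    for i in range(h):
        for j in range(w):
            eroded[i, j] = min(
                padded[i + r_int + dy, j + r_int + dx] - hh for dy, dx, hh in offsets
            )
    padded = np.pad(eroded, r_int, mode="edge")
    opened = np.empty_like(pixels, dtype=float)
    for i in range(h):
        for j in range(w):
            opened[i, j] = max(
                padded[i + r_int + dy, j + r_int + dx] + hh for dy, dx, hh in offsets
            )
    return opened


def brute_background_subtract(pixels: np.ndarray, radius: float) -> np.ndarray:
    bg = np.clip(brute_ball_opening(pixels, radius), 0.0, None)
    return np.clip(pixels - bg, 0.0, None)


def sampled_gaussian_kernel(sigma: float, truncate: float = 4.0) -> np.ndarray:
    """2-D Gaussian kernel sampled on the integer grid, truncated at
    ``truncate``·σ per axis, normalized to sum 1 (separable construction)."""
    r = int(truncate * sigma + 0.5)
    x = np.arange(-r, r + 1, dtype=float)
    g1 = np.exp(-0.5 * (x / sigma) ** 2)
    g1 /= g1.sum()
    return np.outer(g1, g1)


def brute_convolve_same(pixels: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Direct 'same'-size convolution with edge replication, by kernel sums."""
    kr = kernel.shape[0] // 2
    padded = np.pad(pixels, kr, mode="edge")
    h, w = pixels.shape
    out = np.empty_like(pixels, dtype=float)
    for i in range(h):
        for j in range(w):
            out[i, j] = float((padded[i : i + 2 * kr + 1, j : j + 2 * kr + 1] * kernel).sum())
    return out


def brute_median_cross(pixels: np.ndarray, radius: float) -> np.ndarray:
    """Per-pixel median over the circular neighborhood dx²+dy² ≤ r², with
    edge replication."""
    r_int = math.ceil(radius)
    offsets = [
        (dy, dx)
        for dy in range(-r_int, r_int + 1)
        for dx in range(-r_int, r_int + 1)
        if dy * dy + dx * dx <= radius * radius
    ]
    padded = np.pad(pixels, r_int, mode="edge")
    h, w = pixels.shape
    out = np.empty_like(pixels, dtype=float)
    for i in range(h):
        for j in range(w):
            vals = [padded[i + r_int + dy, j + r_int + dx] for dy, dx in offsets]
            out[i, j] = float(np.median(vals))
    return out


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[set[tuple[int, int]]]:
    """Connected components of a boolean mask by BFS flood fill."""
    if connectivity == 4:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        neigh = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                comp = set()
                q = deque([(i, j)])
                seen[i, j] = True
                while q:
                    y, x = q.popleft()
                    comp.add((y, x))
                    for dy, dx in neigh:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            q.append((ny, nx))
                comps.append(comp)
    return comps


# ----------------------------------------------------------------------------
# helpers / fixtures


def gray(pixels, pixel_size_um: float = PIXEL_SIZE_UM) -> GrayImage:
    return GrayImage(pixels=np.asarray(pixels, dtype=float), pixel_size_um=pixel_size_um)


@pytest.fixture(scope="session")
def compact_chain() -> PreprocessParams:
    """Preprocessing chain of the compact (quarter-scale) study."""
    return PreprocessParams(background_radius_px=COMPACT_BACKGROUND_RADIUS_PX)


def quantify_compact(img: GrayImage, chain: PreprocessParams) -> ImageStats:
    """Full per-image pipeline (compact chain): preprocess → mean threshold →
    label → 10 µm² filter → stats."""
    pre = preprocess(img, chain)
    objects = filter_min_size(label_objects(threshold_mean(pre)), 10.0)
    return image_stats(objects)


@pytest.fixture(scope="session")
def compact_field() -> FieldParams:
    return compact_field_params(seed=11)
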
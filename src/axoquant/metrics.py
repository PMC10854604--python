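"""Normalized degeneration statistics and well-level quality control.

Two statistics summarize degeneration of a neurite field relative to a pair
of reference image sets:

* **Fragmentation [%]** — from object counts. Intact references define 0%,
  fully degenerated references (recorded > 18 h after the cut) define 100%::

      fragmentation = (count_sample − count_intact) / (count_cut − count_intact) · 100

* **Integrity [% of intact]** — from the average object size, logarithmized
  for variance stabilization. The fully degenerated reference is the 0%
  baseline, the intact reference 100%::

      integrity = (log size_sample − log size_cut) / (log size_intact − log size_cut) · 100

Neither statistic is clamped to [0, 100]: samples sparser than the intact
reference or coarser than the degenerated reference legitimately fall
outside the range. The logarithm base is immaterial (ratio of log
differences); natural log is used internally.

Well QC: a sample well is evaluable only if its neurite-covered area exceeds
70% of the intact reference area (strict inequality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import fmean
from typing import Literal, Sequence

from .errors import DomainError, InputError, ReferenceValidityError
from .segment import ImageStats

__all__ = [
    "ReferenceStats",
    "DegenerationResult",
    "fragmentation",
    "integrity",
    "qc_area",
    "aggregate_well",
    "build_reference_stats",
]

AggregationMode = Literal["per_image_mean", "pooled"]


@dataclass(frozen=True)
class ReferenceStats:
    """Aggregated statistics of the intact and fully-degenerated reference sets.

    ``count_*`` are mean per-image object counts; ``size_*`` mean per-image
    average object sizes (µm²); ``area_intact`` the mean total object area of
    the intact set (µm²), the denominator of the QC area ratio.
    """

    count_intact: float
    count_cut: float
    size_intact: float
    size_cut: float
    area_intact: float

    def __post_init__(self) -> None:
        if not self.count_cut > self.count_intact:
            raise ReferenceValidityError(
                f"count_cut ({self.count_cut}) must exceed count_intact ({self.count_intact})"
            )
        if not self.size_cut > 0:
            raise ReferenceValidityError(f"size_cut must be positive, got {self.size_cut}")
        if not self.size_intact > self.size_cut:
            raise ReferenceValidityError(
                f"size_intact ({self.size_intact}) must exceed size_cut ({self.size_cut})"
            )
        if not self.area_intact > 0:
            raise ReferenceValidityError(f"area_intact must be positive, got {self.area_intact}")


@dataclass(frozen=True)
class DegenerationResult:
    """Per-well outcome: the two normalized statistics, the QC area ratio and
    the aggregated raw inputs they were computed from."""

    fragmentation_pct: float
    integrity_pct: float  # NaN when no image had objects
    area_ratio: float
    qc_pass: bool
    n_images: int
    count_sample: float
    size_sample_um2: float
    total_area_um2: float


def fragmentation(count_sample: float, refs: ReferenceStats) -> float:
    """Fragmentation [%]: object count normalized between the intact (0%)
    and fully degenerated (100%) references. Not clamped."""
    if count_sample < 0:
        raise DomainError(f"count_sample must be non-negative, got {count_sample}")
    return (count_sample - refs.count_intact) / (refs.count_cut - refs.count_intact) * 100.0

def integrity(size_sample: float, refs: ReferenceStats) -> float:
    """Integrity [% of intact]: log average object size normalized between the
    degenerated (0%) and intact (100%) references.

    NaN in → NaN out (an object-free sample has no defined average size).
    Not clamped.
    """
    if math.isnan(size_sample):
        return math.nan
    if size_sample <= 0:
        raise DomainError(f"size_sample must be positive, got {size_sample}")
    return (
        (math.log(size_sample) - math.log(refs.size_cut))
        / (math.log(refs.size_intact) - math.log(refs.size_cut))
        * 100.0
    )


def qc_area(
    total_area_sample: float, refs: ReferenceStats, threshold: float = 0.70
) -> tuple[float, bool]:
    """Neurite-covered-area QC: ratio of sample total object area to the
    intact reference area, passing when strictly above ``threshold``."""
    if not 0.0 < threshold <= 1.0:
        raise DomainError(f"qc threshold must lie in (0, 1], got {threshold}")
    ratio = total_area_sample / refs.area_intact
    return ratio, ratio > threshold


def _mean_stats(per_image: Sequence[ImageStats], mode: AggregationMode) -> tuple[float, float, float]:
    """(mean count, mean size, mean total area) of an image set.

    per_image_mean: the size is the mean of per-image average sizes over
    images that contain at least one object (a missing per-image average does
    not zero-dilute the mean). pooled: the size is the grand total area
    divided by the grand object count, as if all objects of the set were in
    one image.
    """
    if not per_image:
        raise InputError("image set is empty")
    count = fmean(s.count for s in per_image)
    total = fmean(s.total_area_um2 for s in per_image)
    if mode == "per_image_mean":
        sizes = [s.mean_size_um2 for s in per_image if s.has_objects]
        size = fmean(sizes) if sizes else math.nan
    elif mode == "pooled":
        n_objects = sum(s.count for s in per_image)
        size = sum(s.total_area_um2 for s in per_image) / n_objects if n_objects else math.nan
    else:
        raise InputError(f"unknown aggregation mode: {mode}")
    return count, size, total


def aggregate_well(
    per_image_stats: Sequence[ImageStats],
    refs: ReferenceStats,
    qc_threshold: float = 0.70,
    mode: AggregationMode = "per_image_mean",
) -> DegenerationResult:
    """Aggregate the per-image statistics of one well and evaluate both
    metrics plus the area QC against the references.

    Object-free images contribute to counts and areas but are excluded from
    the size mean (their average size is undefined).
    """
    count_sample, size_sample, total_sample = _mean_stats(per_image_stats, mode)
    frag = fragmentation(count_sample, refs)
    integ = integrity(size_sample, refs)
    ratio, qc_pass = qc_area(total_sample, refs, threshold=qc_threshold)
    return DegenerationResult(
        fragmentation_pct=frag,
        integrity_pct=integ,
        area_ratio=ratio,
        qc_pass=qc_pass,
        n_images=len(per_image_stats),
        count_sample=count_sample,
        size_sample_um2=size_sample,
        total_area_um2=total_sample,
    )


def build_reference_stats(
    intact_image_stats: Sequence[ImageStats],
    cut_image_stats: Sequence[ImageStats],
    mode: AggregationMode = "per_image_mean",
) -> ReferenceStats:
    """Build :class:`ReferenceStats` from the intact and fully-degenerated
    reference image sets; raises :class:`ReferenceValidityError` naming the
    violated inequality if the sets are not usable as normalization anchors."""
    count_intact, size_intact, area_intact = _mean_stats(intact_image_stats, mode)
    count_cut, size_cut, _ = _mean_stats(cut_image_stats, mode)
    if math.isnan(size_intact) or math.isnan(size_cut):
        raise ReferenceValidityError("a reference set contains no objects at all")
    return ReferenceStats(
        count_intact=count_intact,
        count_cut=count_cut,
        size_intact=size_intact,
        size_cut=size_cut,
        area_intact=area_intact,
    )
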
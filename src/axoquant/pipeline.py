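"""Batch orchestration: directory ingestion, per-well quantification against
reference sets, synthetic-tree generation, result and provenance writing.

Directory convention: the input tree holds one subdirectory per well; the
TIFF/PNG files inside are the recorded fields, processed in lexicographic
order. The intact and fully-degenerated reference wells are designated in
the configuration by name.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import segment
from .config import RunConfig
from .errors import AxoquantError, ConfigurationError, InputError
from .image import GrayImage, read_image, write_image
from .metrics import ReferenceStats, aggregate_well, build_reference_stats
from .preprocess import preprocess
from .segment import ImageStats
from .synthgen import (
    DegenerationParams,
    FieldParams,
    KineticsParams,
    frag_degree_at,
    generate_timecourse,
)

logger = logging.getLogger(__name__)

__all__ = ["QuantifyOutput", "SimSpec", "run_quantify", "run_simulate", "quantify_image"]

IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}

WELL_COLUMNS = [
    "well_id",
    "time_h",
    "n_images",
    "count_sample",
    "size_sample_um2",
    "total_area_um2",
    "fragmentation_pct",
    "integrity_pct",
    "area_ratio",
    "qc_pass",
    "config_hash",
]


@dataclass
class QuantifyOutput:
    """Everything a run produced: per-well results, per-image raw statistics,
    the references used, and the list of files that failed to process."""

    wells: pd.DataFrame
    images: pd.DataFrame
    refs: ReferenceStats
    failed_files: list[str] = field(default_factory=list)

    @property
    def partial_failure(self) -> bool:
        return bool(self.failed_files)


def quantify_image(img: GrayImage, config: RunConfig) -> tuple[ImageStats, float]:
    """Run one image through preprocess → threshold → particle analysis.

    Returns the image statistics and the mean threshold that was applied
    (logged per image for provenance).
    """
    conditioned = preprocess(img, config.preprocess_params())
    mask = segment.threshold_mean(conditioned)
    objects = segment.label_objects(mask, connectivity=config.connectivity)
    objects = segment.filter_min_size(objects, min_area_um2=config.min_area_um2)
    return segment.image_stats(objects), float(mask.threshold)


def _well_dirs(tree: Path) -> list[Path]:
    return sorted(p for p in tree.iterdir() if p.is_dir())


def _well_images(well_dir: Path) -> list[Path]:
    return sorted(p for p in well_dir.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)


def _process_well(
    well_dir: Path, config: RunConfig, failed: list[str], debug_dir: Path | None
) -> list[dict]:
    records = []
    for path in _well_images(well_dir):
        try:
            img = read_image(path, pixel_size_um=config.pixel_size_um)
            if debug_dir is not None:
                conditioned = preprocess(img, config.preprocess_params())
                write_image(debug_dir / f"{well_dir.name}_{path.stem}_pre.tif", conditioned)
            stats, threshold = quantify_image(img, config)
        except (AxoquantError, OSError, ValueError) as exc:
            logger.error("failed to process %s: %s", path, exc)
            failed.append(str(path))
            continue
        records.append(
            {
                "well_id": well_dir.name,
                "image": path.name,
                "threshold": threshold,
                "count": stats.count,
                "mean_size_um2": stats.mean_size_um2,
                "total_area_um2": stats.total_area_um2,
            }
        )
    return records


def run_quantify(config: RunConfig, image_tree: str | Path) -> QuantifyOutput:
    """Quantify every well of an image tree against its reference sets.

    Reference statistics are built from the wells named in
    ``config.intact_wells`` / ``config.cut_wells`` (pooling their images);
    every well in the tree, references included, is then scored. Unreadable
    files are logged, skipped, and reported in ``failed_files``.
    """
    tree = Path(image_tree)
    if not tree.is_dir():
        raise InputError(f"image tree not found: {tree}")
    wells = _well_dirs(tree)
    names = {w.name for w in wells}
    if not config.intact_wells or not config.cut_wells:
        raise ConfigurationError("intact_wells and cut_wells must both be designated")
    for ref in [*config.intact_wells, *config.cut_wells]:
        if ref not in names:
            raise ConfigurationError(f"designated reference well '{ref}' not in tree")

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    debug_dir = None
    if config.debug_images:
        debug_dir = out_dir / "debug"
        debug_dir.mkdir(exist_ok=True)

    failed: list[str] = []
    image_records: dict[str, list[dict]] = {}
    for well in wells:
        image_records[well.name] = _process_well(well, config, failed, debug_dir)

    def stats_of(well_names: list[str]) -> list[ImageStats]:
        out = []
        for name in well_names:
            for rec in image_records[name]:
                out.append(
                    ImageStats(
                        count=rec["count"],
                        mean_size_um2=rec["mean_size_um2"],
                        total_area_um2=rec["total_area_um2"],
                    )
                )
        return out

    refs = build_reference_stats(
        stats_of(config.intact_wells), stats_of(config.cut_wells), mode=config.aggregation
    )

    config_hash = config.config_hash()
    rows = []
    for well in wells:
        recs = image_records[well.name]
        if not recs:
            logger.warning("well %s has no readable images; skipped", well.name)
            continue
        result = aggregate_well(
            stats_of([well.name]), refs, qc_threshold=config.qc_threshold, mode=config.aggregation
        )
        rows.append(
            {
                "well_id": well.name,
                "time_h": config.time_from_well(well.name),
                "n_images": result.n_images,
                "count_sample": result.count_sample,
                "size_sample_um2": result.size_sample_um2,
                "total_area_um2": result.total_area_um2,
                "fragmentation_pct": result.fragmentation_pct,
                "integrity_pct": result.integrity_pct,
                "area_ratio": result.area_ratio,
                "qc_pass": result.qc_pass,
                "config_hash": config_hash,
            }
        )

    wells_df = pd.DataFrame(rows, columns=WELL_COLUMNS)
    images_df = pd.DataFrame(
        [r for recs in image_records.values() for r in recs],
        columns=["well_id", "image", "threshold", "count", "mean_size_um2", "total_area_um2"],
    )

    wells_df.to_csv(out_dir / "wells.csv", index=False)
    images_df.to_csv(out_dir / "images.csv", index=False)
    metadata = {
        "config": asdict(config),
        "config_hash": config_hash,
        "references": asdict(refs),
        "n_wells": len(wells_df),
        "failed_files": failed,
    }
    (out_dir / "run.json").write_text(json.dumps(metadata, indent=2, default=str))
    return QuantifyOutput(wells=wells_df, images=images_df, refs=refs, failed_files=failed)


# ----------------------------------------------------------------------------
# synthetic-tree generation


@dataclass
class SimSpec:
    """What to simulate: a time course of wells, ``n_fields`` images each.

    ``field_params`` carries geometry/photometry; per-field seeds are derived
    from its seed, so one spec is fully reproducible. The first and last time
    points serve as the intact and fully-degenerated reference wells of the
    written tree.
    """

    field_params: FieldParams = field(default_factory=FieldParams)
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    times_h: tuple[float, ...] = (0.0, 6.0, 8.0, 12.0, 18.0, 24.0)
    n_fields: int = 3
    bead_spacing_um: float = 10.0
    bead_radius_um: float = 1.5
    mass_conserve: bool = True

    def __post_init__(self) -> None:
        if self.n_fields < 1:
            raise InputError("n_fields must be ≥ 1")
        if len(self.times_h) < 2:
            raise InputError("at least two time points are required")


def _well_name(time_h: float) -> str:
    return f"t{time_h:05.1f}h"


def run_simulate(spec: SimSpec, out_tree: str | Path) -> pd.DataFrame:
    """Write a ready-to-quantify synthetic image tree plus its ground truth.

    Layout: one well directory per time point (``t006.0h`` …), each holding
    ``n_fields`` 16-bit TIFF frames that share track geometry across time
    points (a time-lapse per field index). Returns (and writes) the
    ground-truth table: one row per frame with the true frag_degree and
    breakpoint count.
    """
    tree = Path(out_tree)
    tree.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence([int(spec.field_params.seed), 3])
    field_seeds = [int(s) for s in ss.generate_state(spec.n_fields) >> np.uint32(1)]

    gt_rows = []
    for i, fseed in enumerate(field_seeds):
        params = FieldParams(**{**asdict(spec.field_params), "seed": fseed})
        base_dp = DegenerationParams(
            frag_degree=0.0,
            bead_spacing_um=spec.bead_spacing_um,
            bead_radius_um=spec.bead_radius_um,
            mass_conserve=spec.mass_conserve,
            seed=fseed,
        )
        frames = generate_timecourse(
            params, kinetics=spec.kinetics, times_h=spec.times_h, degen_params=base_dp
        )
        for t, (img, gt) in zip(spec.times_h, frames):
            well_dir = tree / _well_name(t)
            well_dir.mkdir(exist_ok=True)
            name = f"field{i:02d}.tif"
            write_image(well_dir / name, img, dtype="uint16")
            gt_rows.append(
                {
                    "well_id": well_dir.name,
                    "image": name,
                    "time_h": t,
                    "field_index": i,
                    "field_seed": fseed,
                    "frag_degree": gt.frag_degree,
                    "n_breakpoints": gt.n_breakpoints,
                }
            )

    gt_df = pd.DataFrame(gt_rows)
    gt_df.to_csv(tree / "ground_truth.csv", index=False)

    config = RunConfig(
        pixel_size_um=spec.field_params.pixel_size_um,
        intact_wells=[_well_name(spec.times_h[0])],
        cut_wells=[_well_name(spec.times_h[-1])],
        seed=spec.field_params.seed,
    )
    config.to_yaml(tree / "config.yaml")
    return gt_df


def expected_frag_degrees(spec: SimSpec) -> list[float]:
    """Logistic frag_degree at each of the spec's time points."""
    return [frag_degree_at(t, spec.kinetics) for t in spec.times_h]
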
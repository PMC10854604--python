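"""Run configuration: every tunable of the quantification chain in one
serializable record, with the published defaults."""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .metrics import AggregationMode
from .preprocess import PreprocessParams

__all__ = ["RunConfig"]

DEFAULT_TIME_REGEX = r"t(?P<time>[0-9]+(?:\.[0-9]+)?)h"


@dataclass
class RunConfig:
    """Parameters of one quantification run.

    ``pixel_size_um`` is required (no silent default: the 10 µm² size cutoff
    is meaningless without it). Filter parameters default to the published
    chain: rolling-ball radius 50 px, unsharp weight 0.6 / radius 2 px,
    median radius 1 px, mean threshold, 8-connectivity, 10 µm² minimum object
    size, QC at > 70% of intact area.
    """

    pixel_size_um: float
    background_radius_px: float = 50.0
    unsharp_radius_px: float = 2.0
    unsharp_weight: float = 0.6
    median_radius_px: float = 1.0
    connectivity: int = 8
    min_area_um2: float = 10.0
    qc_threshold: float = 0.70
    intact_wells: list[str] = field(default_factory=list)
    cut_wells: list[str] = field(default_factory=list)
    aggregation: AggregationMode = "per_image_mean"
    output_dir: str = "results"
    debug_images: bool = False
    time_regex: str = DEFAULT_TIME_REGEX
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pixel_size_um > 0:
            raise ConfigurationError("pixel_size_um must be positive")
        if self.connectivity not in (4, 8):
            raise ConfigurationError("connectivity must be 4 or 8")
        if not 0 < self.qc_threshold <= 1:
            raise ConfigurationError("qc_threshold must lie in (0, 1]")
        if self.aggregation not in ("per_image_mean", "pooled"):
            raise ConfigurationError(f"unknown aggregation mode: {self.aggregation}")

    # -- derived views -------------------------------------------------------

    def preprocess_params(self) -> PreprocessParams:
        return PreprocessParams(
            background_radius_px=self.background_radius_px,
            unsharp_radius_px=self.unsharp_radius_px,
            unsharp_weight=self.unsharp_weight,
            median_radius_px=self.median_radius_px,
        )

    def config_hash(self) -> str:
        """Short digest of the analysis-relevant parameters; stamped on every
        result row so any parameter change is visible in the provenance.
        Output location and debug flags do not affect results and are
        excluded."""
        payload = asdict(self)
        payload.pop("output_dir")
        payload.pop("debug_images")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def time_from_well(self, well_id: str) -> float | None:
        """Extract the post-axotomy time (h) encoded in a well name, if any."""
        m = re.search(self.time_regex, well_id)
        if m:
            try:
                return float(m.group("time"))
            except (IndexError, ValueError):
                return None
        return None

    # -- serialization -------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigurationError(f"{path}: {exc}") from exc
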
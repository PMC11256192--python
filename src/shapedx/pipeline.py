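"""End-to-end orchestration: paired images -> diagnosis report.

The measurement path for one image is segmentation -> per-cell descriptors
-> solidity filter -> 10-bin roundness distribution -> (P1, P2) feature
point.  A sample pairs one slow-deoxygenation (C_low) image with one fast
(C_high) image; the two regions under the linear boundary feed the decision
matrix.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from dataclasses import dataclass, field

from . import __version__
from .classifier import (
    Diagnosis,
    LinearBoundary,
    diagnose,
    load_boundary,
    published_boundary,
    region_of,
)
from .distribution import RoundnessDistribution, build_distribution, distribution_table
from .featurespace import COMBINATION_10, RangeCombination, feature_point
from .imaging import ImageGrid, SegmentationParams, load_image, segment_field
from .shape_features import (
    SOLIDITY_MIN,
    descriptor_table,
    filter_cells,
    measure_regions,
)
from .synth import PIXELS_PER_MICRON, SyntheticField

__all__ = ["RunConfig", "measure_image", "field_distribution", "run_diagnosis"]

MIN_CONFIDENT_CELLS = 50


@dataclass
class RunConfig:
    pixel_scale: float = PIXELS_PER_MICRON
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    solidity_min: float = SOLIDITY_MIN
    combination: RangeCombination = COMBINATION_10
    boundary_source: str = "published"  # "published" or a model-file path
    seed: int = 0
    min_cells: int = MIN_CONFIDENT_CELLS

    def boundary(self) -> LinearBoundary:
        if self.boundary_source == "published":
            return published_boundary()
        return load_boundary(self.boundary_source)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["combination"] = {
            "p1_range": list(self.combination.p1_range),
            "p2_range": list(self.combination.p2_range),
            "index": self.combination.index,
        }
        return d


def measure_image(image: ImageGrid, config: RunConfig | None = None):
    """Segment and measure one image.

    Returns (distribution, kept descriptors, all descriptors, regions).
    """
    config = config or RunConfig()
    regions = segment_field(image, config.segmentation)
    cells = measure_regions(regions, image.pixel_scale)
    kept = filter_cells(cells, config.solidity_min)
    if not kept:
        raise ValueError("no cells survived segmentation and the solidity filter")
    dist = build_distribution([c.roundness for c in kept])
    return dist, kept, cells, regions


def field_distribution(
    fld: SyntheticField, config: RunConfig | None = None
) -> RoundnessDistribution:
    """Full measurement pipeline applied to an in-memory synthetic field."""
    grid = ImageGrid(pixels=fld.image, pixel_scale=fld.pixel_scale)
    dist, _, _, _ = measure_image(grid, config)
    return dist


def run_diagnosis(
    image_low,
    image_high,
    config: RunConfig | None = None,
    sample_id: str = "sample",
    out_dir=None,
) -> dict:
    """Diagnose one sample from its paired C_low / C_high images.

    Returns the report dict; when ``out_dir`` is given, also writes
    report.json plus per-cell and distribution CSVs.  The report timestamp
    lives in an isolated metadata field so the rest of the report is
    byte-reproducible for identical inputs and config.
    """
    config = config or RunConfig()
    boundary = config.boundary()

    report: dict = {
        "sample_id": sample_id,
        "software_version": __version__,
        "config": config.to_dict(),
        "conditions": {},
    }
    points = {}
    tables = {}
    for cond, src in (("c_low", image_low), ("c_high", image_high)):
        grid = src if isinstance(src, ImageGrid) else load_image(src, config.pixel_scale)
        dist, kept, cells, _ = measure_image(grid, config)
        pt = feature_point(dist, config.combination, condition=cond, sample_id=sample_id)
        points[cond] = pt
        tables[cond] = (cells, dist)
        report["conditions"][cond] = {
            "n_segmented": len(cells),
            "n_kept": len(kept),
            "low_confidence": len(kept) < config.min_cells,
            "P1": pt.P1,
            "P2": pt.P2,
            "region": region_of(pt, boundary).value,
        }

    result: Diagnosis = diagnose(
        region_low=_region(report, "c_low"), region_high=_region(report, "c_high")
    )
    report["call"] = result.call.value
    report["boundary"] = {
        "slope": boundary.slope,
        "intercept": boundary.intercept,
        "gray_below": boundary.gray_below,
    }

    if out_dir is not None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cond, (cells, dist) in tables.items():
            descriptor_table(cells, config.solidity_min).to_csv(
                out / f"{sample_id}_{cond}_cells.csv", index=False
            )
            distribution_table(dist).to_csv(
                out / f"{sample_id}_{cond}_distribution.csv", index=False
            )
        import datetime

        on_disk = dict(report)
        on_disk["metadata"] = {
            "generated_at": datetime.datetime.now(datetime.timezone.utc).isoformat()
        }
        with open(out / f"{sample_id}_report.json", "w") as fh:
            json.dump(on_disk, fh, indent=2)
    return report


def _region(report: dict, cond: str):
    from .classifier import Region

    return Region(report["conditions"][cond]["region"])
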
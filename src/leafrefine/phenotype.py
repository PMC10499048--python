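"""Phenotype extraction from segmented instances: leaf count and leaf area.

Downstream of instance segmentation, the phenotypic outputs are simply the
number of detected leaves per image and each leaf's area — the mask's
true-pixel count, optionally converted to physical units via a
mm-per-pixel scale (area_mm² = area_px · scale²).  Overlapping instances
are *not* de-duplicated: each contributes its full mask area.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .dataset_io import mask_area
from .evaluate import Prediction

__all__ = ["LeafMeasurement", "PhenotypeReport", "derive_phenotypes", "write_report_csv"]


@dataclass
class LeafMeasurement:
    image_id: int
    leaf_id: int
    score: float
    area_px: int
    area_physical: float | None = None  # mm²


@dataclass
class PhenotypeReport:
    scale: float | None  # mm per pixel
    leaves: list[LeafMeasurement] = field(default_factory=list)

    def leaf_count(self, image_id: int) -> int:
        return sum(1 for m in self.leaves if m.image_id == image_id)

    def counts_by_image(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for m in self.leaves:
            counts[m.image_id] = counts.get(m.image_id, 0) + 1
        return counts

    def areas_by_image(self) -> dict[int, list[int]]:
        areas: dict[int, list[int]] = {}
        for m in self.leaves:
            areas.setdefault(m.image_id, []).append(m.area_px)
        return areas


def derive_phenotypes(
    preds: list[Prediction],
    score_threshold: float = 0.5,
    scale: float | None = None,
) -> PhenotypeReport:
    """Count leaves and measure per-leaf areas from scored predictions.

    Only predictions with ``score >= score_threshold`` count as leaves.
    ``scale`` (mm/pixel) must be positive when given.
    """
    if scale is not None and scale <= 0:
        raise ValueError(f"scale must be positive, got {scale!r}")
    report = PhenotypeReport(scale=scale)
    for k, p in enumerate(preds):
        if p.score < score_threshold:
            continue
        area = mask_area(p.decoded_mask())
        report.leaves.append(
            LeafMeasurement(
                image_id=p.image_id,
                leaf_id=k,
                score=p.score,
                area_px=area,
                area_physical=area * scale * scale if scale is not None else None,
            )
        )
    return report


def write_report_csv(report: PhenotypeReport, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "leaf_id", "score", "area_px", "area_mm2"])
        for m in report.leaves:
            writer.writerow(
                [
                    m.image_id,
                    m.leaf_id,
                    f"{m.score:.6g}",
                    m.area_px,
                    "" if m.area_physical is None else f"{m.area_physical:.6g}",
                ]
            )
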